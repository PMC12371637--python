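"""Clinical-table statistics for a fatigue-stratified cohort.

Subjects are split by the Fatigue Severity Scale cut-off (FSS > 4 =
clinically significant fatigue, "FAT"; otherwise "NFAT"). Group
comparisons follow a normality-routing rule: Shapiro-Wilk on each group
at alpha 0.05 sends a variable to the pooled-variance Student t-test
(both groups normal) or the Mann-Whitney U test; gender is always
compared with a 2x2 chi-square. Pearson correlations (pairwise-complete)
summarize relations among the scales, and a partial correlation gives
the effect size between cluster-mean FC and a symptom score after
covariate adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "pooled_t_from_summary",
    "two_sample_t",
    "mann_whitney_u",
    "chi_square_2x2",
    "pearson_matrix",
    "partial_correlation",
    "route_tests",
    "FSS_CUTOFF",
]

FSS_CUTOFF = 4.0


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" | "mann-whitney" | "chi2"
    statistic: float
    p_value: float


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance Student t from group summaries; df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two subjects")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), n1 + n2 - 2


def two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t with two-tailed Student p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df = pooled_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (greater-than pairs + half-ties) with two-tailed p.

    p comes from exact enumeration when ``n1 * n2 <= 400`` and there are
    no ties, otherwise from the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    diff = x[:, None] - y[None, :]
    u = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return u, float(res.pvalue)


def chi_square_2x2(counts: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (df = 1), no continuity correction
    by default."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(obs < 0) or obs.sum() == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def pearson_matrix(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-tailed p matrices.

    Constant variables yield NaN cells (flagged with a warning) rather
    than an arbitrary value.
    """
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            xa, xb = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(
                    f"constant variable in pair ({a}, {b}); correlation undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(xa, xb)
                rij, pij = res.statistic, res.pvalue
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def partial_correlation(
    a: np.ndarray, b: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Pearson correlation of a and b after least-squares covariate adjustment.

    Both vectors are residualized against the covariates plus an
    intercept; with no covariates this reduces to the plain Pearson r.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    if b.size != n:
        raise ValueError("a and b must have equal length")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates must have N rows")
        if n <= covariates.shape[1] + 2:
            raise ValueError("need N > number of covariates + 2")
        Z = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    proj = Z @ np.linalg.pinv(Z)
    ra = a - proj @ a
    rb = b - proj @ b
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        raise ValueError("degenerate residuals; correlation undefined")
    return float((ra @ rb) / denom)


_DEFAULT_VARIABLES = [
    "age",
    "fss",
    "disease_duration",
    "ledd",
    "pdss2",
    "ess",
    "has",
    "hds",
    "aes",
    "updrs3",
    "moca",
    "eicv",
]


def route_tests(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Full group-comparison report with Shapiro-Wilk normality routing.

    For each variable, both groups (FSS > 4 vs not) are tested for
    normality; a t-test is used when both pass at ``alpha``, otherwise
    Mann-Whitney. Gender is always chi-square. Groups smaller than 3
    fall back to Mann-Whitney with a warning.
    """
    if "fss" not in table.columns:
        raise ValueError("table must contain an 'fss' column")
    fat = table[table["fss"] > FSS_CUTOFF]
    nfat = table[table["fss"] <= FSS_CUTOFF]
    if len(fat) == 0 or len(nfat) == 0:
        raise ValueError("both FAT and NFAT groups must be nonempty")
    if variables is None:
        variables = [v for v in _DEFAULT_VARIABLES if v in table.columns]
    out: list[GroupComparison] = []
    if "gender" in table.columns:
        counts = np.array(
            [
                [(nfat["gender"] == 0).sum(), (nfat["gender"] == 1).sum()],
                [(fat["gender"] == 0).sum(), (fat["gender"] == 1).sum()],
            ]
        )
        chi2, p = chi_square_2x2(counts)
        out.append(GroupComparison("gender", "chi2", chi2, p))
    for var in variables:
        x = nfat[var].dropna().to_numpy(float)
        y = fat[var].dropna().to_numpy(float)
        if min(x.size, y.size) < 3:
            warnings.warn(
                f"group size below 3 for {var}; falling back to Mann-Whitney",
                RuntimeWarning,
                stacklevel=2,
            )
            normal = False
        else:
            normal = (
                stats.shapiro(x).pvalue >= alpha and stats.shapiro(y).pvalue >= alpha
            )
        if normal:
            t, _, p = two_sample_t(x, y)
            out.append(GroupComparison(var, "t", t, p))
        else:
            u, p = mann_whitney_u(x, y)
            out.append(GroupComparison(var, "mann-whitney", u, p))
    return out
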