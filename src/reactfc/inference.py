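"""Permutation-based group inference with TFCE and FWE control.

The group model is an ordinary least-squares GLM fitted independently at
every voxel; a single contrast (the explanatory variable of interest,
e.g. fatigue score or group) is tested while the remaining columns act
as nuisance covariates. Null distributions come from Freedman-Lane
permutation: residuals of the nuisance-only model are row-permuted, the
nuisance fit is added back, and the full-model contrast t is recomputed.

Voxelwise t-maps are enhanced with threshold-free cluster enhancement
(TFCE) before familywise-error correction against the permutation
distribution of the image-wide maximum TFCE value. With few
permutations the extreme tail is optionally refined by fitting a
generalized Pareto distribution (GPD) to the exceedances of the null
maximum over its 90th percentile.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DesignSpec",
    "TFCEParams",
    "InferenceResult",
    "ModelSpec",
    "build_design",
    "fit_glm_voxelwise",
    "tfce_transform",
    "freedman_lane_draw",
    "permutation_fwe",
    "gpd_tail_pvalue",
    "run_models",
]


@dataclass
class DesignSpec:
    """Group-level design: matrix, contrast, and nuisance partition.

    ``nuisance_idx`` lists the columns treated as nuisance under
    Freedman-Lane (the intercept belongs there); contrast-bearing
    columns must not appear in it.
    """

    design: np.ndarray
    contrast: np.ndarray
    nuisance_idx: tuple[int, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2D (N, P)")
        n, p = self.design.shape
        if self.contrast.shape != (p,):
            raise ValueError("contrast length must equal the design column count")
        if not np.any(self.contrast):
            raise ValueError("contrast must be nonzero")
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")
        bearing = set(np.flatnonzero(self.contrast))
        if bearing & set(self.nuisance_idx):
            raise ValueError("nuisance set must exclude contrast-bearing columns")

    @property
    def n_subjects(self) -> int:
        return self.design.shape[0]


@dataclass
class TFCEParams:
    """TFCE settings: height exponent H, extent exponent E, connectivity C.

    ``dh`` fixes the threshold step; when None the step is
    ``max/n_steps`` (fraction-of-max rule).
    """

    h: float = 2.0
    e: float = 2.0
    connectivity: int = 6
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.h < 0 or self.e < 0:
            raise ValueError("H and E must be nonnegative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class InferenceResult:
    """Observed maps, FWE p-values and the permutation null of the maximum."""

    tmap: np.ndarray
    tfce_map: np.ndarray
    pmap: np.ndarray
    null_max: np.ndarray
    seed: int | None
    n_permutations: int
    tail_diagnostics: dict = field(default_factory=dict)

    @property
    def min_p(self) -> float:
        return float(self.pmap.min())

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        return self.pmap < alpha


# ---------------------------------------------------------------------------
# GLM


def _glm_context(spec: DesignSpec):
    X = spec.design
    c = spec.contrast
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    cvar = float(c @ xtx_inv @ c)
    dof = X.shape[0] - X.shape[1]
    return X, c, pinv, cvar, dof


def _tstats(Y: np.ndarray, X, c, pinv, cvar, dof) -> np.ndarray:
    """Contrast t-statistics for responses ``Y`` of shape (N, V)."""
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    num = c @ beta
    den = np.sqrt(sigma2 * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return t


def fit_glm_voxelwise(maps: np.ndarray, spec: DesignSpec) -> np.ndarray:
    """Voxelwise OLS contrast t-map for subject-by-voxel data.

    ``maps`` is (N, V); the return is the length-V t-map with
    ``df = N - P``.
    """
    Y = np.asarray(maps, dtype=float)
    if Y.ndim != 2:
        raise ValueError("maps must be (N, V)")
    n, p = spec.design.shape
    if Y.shape[0] != n:
        raise ValueError("row count of maps must match the design")
    if n <= p:
        raise ValueError(f"need N > P; got N={n}, P={p}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("maps contain missing or non-finite values")
    X, c, pinv, cvar, dof = _glm_context(spec)
    return _tstats(Y, X, c, pinv, cvar, dof)


# ---------------------------------------------------------------------------
# TFCE


try:  # optional fast path; the scipy route below is the reference
    from ._tfce_fast import tfce_accumulate as _tfce_accumulate_fast
except ImportError:  # pragma: no cover - numba is an ordinary dependency
    _tfce_accumulate_fast = None


def _tfce_scipy(pos: np.ndarray, heights: np.ndarray, dh: float, params) -> np.ndarray:
    """Reference accumulation: connected-component labeling per threshold."""
    out = np.zeros_like(pos)
    structure = params.structure()
    for h in heights:
        maskh = pos >= h
        if not maskh.any():
            break
        labels, _ = ndimage.label(maskh, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[maskh] += (sizes[labels[maskh]] ** params.e) * (h ** params.h) * dh
    return out


def tfce_transform(statmap: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    ``TFCE(v) = sum_h e_h(v)^E * h^H * dh`` over thresholds h, where
    ``e_h(v)`` is the voxel count of the C-connected component
    containing v after thresholding at h. Thresholds follow the midpoint
    rule ``h_i = (i - 1/2) dh`` so the single-voxel closed form
    ``h_max^(H+1)/(H+1)`` is matched to second order. Only positive
    values contribute; test the opposite contrast for negative effects.

    The default implementation is a union-find sweep over descending
    thresholds (compiled with numba); it is exactly equivalent to
    per-threshold component labeling.
    """
    stat = np.asarray(statmap, dtype=float)
    if stat.ndim != 3:
        raise ValueError("statmap must be 3D")
    if not np.all(np.isfinite(stat)):
        raise ValueError("statmap must be finite")
    pos = np.where(stat > 0, stat, 0.0)
    vmax = pos.max()
    if vmax <= 0:
        return np.zeros_like(pos)
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    n_steps = int(math.ceil(vmax / dh))
    heights = (np.arange(1, n_steps + 1) - 0.5) * dh
    heights = heights[heights <= vmax]  # empty top steps contribute nothing
    if _tfce_accumulate_fast is not None:
        flat = _tfce_accumulate_fast(
            np.ascontiguousarray(pos, dtype=np.float64),
            heights,
            float(dh),
            float(params.h),
            float(params.e),
            params.connectivity,
        )
        return flat.reshape(pos.shape)
    return _tfce_scipy(pos, heights, dh, params)


# ---------------------------------------------------------------------------
# Freedman-Lane permutation


def _fl_context(maps: np.ndarray, spec: DesignSpec):
    """Precompute the nuisance-model hat pieces for Freedman-Lane draws."""
    Y = np.asarray(maps, dtype=float)
    n = Y.shape[0]
    if spec.nuisance_idx:
        Z = spec.design[:, list(spec.nuisance_idx)]
        Hz = Z @ np.linalg.pinv(Z)
        fitted = Hz @ Y
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted
    return fitted, resid


def _fl_tstat(fitted, resid, perm, glm_ctx) -> np.ndarray:
    Ystar = fitted + resid[perm]
    return _tstats(Ystar, *glm_ctx)


def freedman_lane_draw(
    maps: np.ndarray,
    spec: DesignSpec,
    rng: np.random.Generator | None = None,
    perm: np.ndarray | None = None,
) -> np.ndarray:
    """One Freedman-Lane permuted t-map.

    Residuals of the nuisance-only fit are row-permuted (by ``perm`` if
    given, else a uniform draw from ``rng``), the nuisance fit is added
    back, and the full-model contrast t is recomputed. The identity
    permutation reproduces the observed t-map exactly.
    """
    Y = np.asarray(maps, dtype=float)
    if perm is None:
        if rng is None:
            raise ValueError("provide either a permutation or an rng")
        perm = rng.permutation(Y.shape[0])
    fitted, resid = _fl_context(Y, spec)
    glm_ctx = _glm_context(spec)
    return _fl_tstat(fitted, resid, np.asarray(perm), glm_ctx)


def permutation_fwe(
    maps: np.ndarray,
    spec: DesignSpec,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 500,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    exhaustive: bool = False,
    tail_approximation: bool = False,
) -> InferenceResult:
    """Voxelwise permutation test with TFCE and max-statistic FWE control.

    Parameters
    ----------
    maps : ndarray
        Subject stack ``(N, nx, ny, nz)``.
    spec : DesignSpec
        Design, contrast and nuisance partition.
    n_perm : int
        Number of random Freedman-Lane draws (ignored when
        ``exhaustive``); the smallest attainable p is ``1/(n_perm+1)``.
    seed : int
        Required for random permutations (reproducibility contract).
    mask : ndarray of bool, optional
        Analysis mask; voxels outside are excluded entirely.
    exhaustive : bool
        Enumerate all N! permutations (N <= 8); p-values are then exact,
        ``p = #{null >= obs} / N!`` with the identity included.
    tail_approximation : bool
        Refine p-values <= 0.10 with a GPD fit to the null-maximum tail.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (N, nx, ny, nz)")
    n = maps.shape[0]
    vol_shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    Y = maps.reshape(n, -1)[:, mask.ravel()]

    glm_ctx = _glm_context(spec)
    fitted, resid = _fl_context(Y, spec)

    def tfce_of(tflat: np.ndarray) -> np.ndarray:
        vol = np.zeros(vol_shape)
        vol[mask] = tflat
        return tfce_transform(vol, params)

    t_obs = _tstats(Y, *glm_ctx)
    tfce_obs = tfce_of(t_obs)

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration supported only for N <= 8")
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        if seed is None:
            raise ValueError("seed is required for random permutations")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_perm))]
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    null_max = np.empty(len(perms))
    for i, perm in enumerate(perms):
        t_perm = _fl_tstat(fitted, resid, perm, glm_ctx)
        null_max[i] = tfce_of(t_perm).max()

    obs_in_mask = tfce_obs[mask]
    exceed = (null_max[None, :] >= obs_in_mask[:, None]).sum(axis=1)
    if exhaustive:
        p_in_mask = exceed / len(perms)
        # guard the open interval contract: identity is in the enumeration,
        # so exceed >= 1 wherever tfce_obs > 0; an all-zero map gives p = 1
        p_in_mask = np.where(obs_in_mask > 0, p_in_mask, 1.0)
    else:
        p_in_mask = (1.0 + exceed) / (1.0 + len(perms))

    diagnostics: dict = {}
    if tail_approximation and not exhaustive:
        tail = _GPDTail(null_max, seed=0 if seed is None else seed)
        diagnostics = tail.diagnostics
        refine = p_in_mask <= 0.10
        if tail.usable and refine.any():
            p_in_mask = p_in_mask.copy()
            p_in_mask[refine] = tail.pvalues(obs_in_mask[refine])

    pmap = np.ones(vol_shape)
    pmap[mask] = p_in_mask
    tvol = np.zeros(vol_shape)
    tvol[mask] = t_obs
    return InferenceResult(
        tmap=tvol,
        tfce_map=tfce_obs,
        pmap=pmap,
        null_max=null_max,
        seed=seed,
        n_permutations=len(perms),
        tail_diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Generalized-Pareto tail approximation


def _anderson_darling_gpd(exc: np.ndarray, shape: float, scale: float) -> float:
    z = np.sort(stats.genpareto.cdf(exc, shape, loc=0, scale=scale))
    z = np.clip(z, 1e-12, 1 - 1e-12)
    m = z.size
    i = np.arange(1, m + 1)
    return float(-m - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


class _GPDTail:
    """ML generalized-Pareto fit to null-maximum exceedances.

    The exceedance threshold is the 90th percentile of the null sample;
    an Anderson-Darling goodness-of-fit check (parametric bootstrap,
    alpha = 0.05) gates the refinement — on rejection callers fall back
    to the empirical p-value.
    """

    def __init__(
        self,
        null: np.ndarray,
        threshold_quantile: float = 0.9,
        alpha: float = 0.05,
        n_boot: int = 199,
        seed: int = 0,
    ) -> None:
        null = np.asarray(null, dtype=float)
        self.null = null
        self.n = null.size
        self.usable = False
        self.diagnostics = {"fit": "not attempted"}
        if self.n < 50:
            self.diagnostics = {"fit": "skipped: null sample below 50"}
            return
        if np.ptp(null) == 0:
            warnings.warn(
                "degenerate null (all values equal); using empirical p only",
                RuntimeWarning,
                stacklevel=3,
            )
            self.diagnostics = {"fit": "skipped: degenerate null"}
            return
        self.u = float(np.quantile(null, threshold_quantile))
        exc = null[null > self.u] - self.u
        if exc.size < 10 or np.ptp(exc) == 0:
            self.diagnostics = {"fit": "skipped: too few distinct exceedances"}
            return
        shape, _, scale = stats.genpareto.fit(exc, floc=0)
        a2 = _anderson_darling_gpd(exc, shape, scale)
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            sim = stats.genpareto.rvs(
                shape, loc=0, scale=scale, size=exc.size, random_state=rng
            )
            s2, _, sc2 = stats.genpareto.fit(sim, floc=0)
            boot[b] = _anderson_darling_gpd(sim, s2, sc2)
        gof_p = float((1 + (boot >= a2).sum()) / (1 + n_boot))
        self.shape, self.scale = float(shape), float(scale)
        self.frac = exc.size / self.n
        self.diagnostics = {
            "fit": "accepted" if gof_p > alpha else "rejected",
            "shape": self.shape,
            "scale": self.scale,
            "threshold": self.u,
            "anderson_darling_A2": a2,
            "gof_p": gof_p,
        }
        self.usable = gof_p > alpha

    def pvalues(self, observed: np.ndarray) -> np.ndarray:
        observed = np.atleast_1d(np.asarray(observed, dtype=float))
        emp = (1.0 + (self.null[None, :] >= observed[:, None]).sum(axis=1)) / (
            1.0 + self.n
        )
        above = observed > self.u
        p = emp.copy()
        if above.any():
            tail = self.frac * stats.genpareto.sf(
                observed[above] - self.u, self.shape, loc=0, scale=self.scale
            )
            # fitted tails with negative shape have bounded support; keep p
            # strictly positive beyond the bound
            p[above] = np.maximum(tail, 1e-16)
        return p


def gpd_tail_pvalue(
    null_max: np.ndarray,
    observed: float,
    threshold_quantile: float = 0.9,
    alpha: float = 0.05,
    n_boot: int = 199,
    seed: int = 0,
) -> float:
    """Tail-refined permutation p-value for one observed statistic.

    If the empirical p exceeds 0.10, or the GPD fit fails its
    Anderson-Darling check, the empirical p-value
    ``(1 + #{null >= obs}) / (1 + n)`` is returned unchanged; otherwise
    the fitted GPD tail probability (scaled by the exceedance fraction)
    replaces it.
    """
    null = np.asarray(null_max, dtype=float)
    if null.size < 50:
        raise ValueError("need a null sample of at least 50 values")
    emp = float((1 + (null >= observed).sum()) / (1 + null.size))
    if emp > 0.10:
        return emp
    tail = _GPDTail(null, threshold_quantile, alpha, n_boot, seed)
    if not tail.usable:
        return emp
    return float(tail.pvalues(np.array([observed]))[0])


# ---------------------------------------------------------------------------
# Model menu


@dataclass
class ModelSpec:
    """One association/group model: predictor of interest + nuisance set."""

    label: str
    predictor: str
    nuisance: tuple[str, ...] = ()


def build_design(
    covariates: pd.DataFrame,
    predictor: str,
    nuisance: tuple[str, ...] = (),
    sign: int = 1,
    label: str = "",
) -> DesignSpec:
    """DesignSpec from a covariate table: intercept + predictor + nuisance.

    Continuous columns are mean-centered (the contrast t is invariant to
    centering, but conditioning improves); binary columns are left as
    0/1. ``sign`` selects the tested direction of the association.
    """
    cols = [predictor, *nuisance]
    missing = covariates[cols].isna()
    if missing.any().any():
        subjects = covariates.index[missing.any(axis=1)].tolist()
        raise ValueError(f"missing covariate values for subjects: {subjects}")
    n = len(covariates)
    parts = [np.ones(n)]
    for c in cols:
        v = covariates[c].to_numpy(dtype=float)
        uniq = np.unique(v)
        if not (uniq.size <= 2 and set(uniq).issubset({0.0, 1.0})):
            v = v - v.mean()
        parts.append(v)
    design = np.column_stack(parts)
    contrast = np.zeros(design.shape[1])
    contrast[1] = float(sign)
    nuisance_idx = (0,) + tuple(range(2, design.shape[1]))
    return DesignSpec(
        design=design,
        contrast=contrast,
        nuisance_idx=nuisance_idx,
        label=label or f"{predictor}~{'+'.join(nuisance) or '1'}",
    )


def run_models(
    enriched: dict[str, np.ndarray],
    covariates: pd.DataFrame,
    models: list[ModelSpec],
    params: TFCEParams = TFCEParams(),
    n_perm: int = 500,
    seed: int = 0,
    mask: np.ndarray | None = None,
    tail_approximation: bool = False,
) -> dict[str, dict[str, dict[str, InferenceResult]]]:
    """Run every model on every system's map stack, both contrast signs.

    ``enriched`` maps system name to an ``(N, nx, ny, nz)`` stack of
    subject beta maps. Results are keyed
    ``[system][model.label]["positive"|"negative"]``; each (system,
    model, sign) cell gets its own child seed derived deterministically
    from ``seed``.
    """
    results: dict[str, dict[str, dict[str, InferenceResult]]] = {}
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(enriched) * len(models) * 2))
    for system, stack in enriched.items():
        results[system] = {}
        for model in models:
            cell: dict[str, InferenceResult] = {}
            for sign, name in ((1, "positive"), (-1, "negative")):
                spec = build_design(
                    covariates,
                    model.predictor,
                    model.nuisance,
                    sign=sign,
                    label=model.label,
                )
                child_seed = int(next(children).generate_state(1)[0] % (2**31))
                cell[name] = permutation_fwe(
                    stack,
                    spec,
                    params=params,
                    n_perm=n_perm,
                    seed=child_seed,
                    mask=mask,
                    tail_approximation=tail_approximation,
                )
            results[system][model.label] = cell
    return results
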