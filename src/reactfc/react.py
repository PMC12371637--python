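"""REACT: receptor-enriched analysis of functional connectivity by targets.

Two-step dual regression. Stage 1 regresses, at every timepoint, the
(volume-wise demeaned) BOLD image on the molecular density templates
used as spatial regressors, yielding one time series per molecular
system — the dominant BOLD fluctuation of that system. Stage 2 regresses
each voxel's time series on those subject-specific series used as
temporal regressors, yielding one beta map per system: the subject's
molecular-enriched functional-connectivity maps.

Both stages demean the response and demean + unit-variance normalize
the regressors, so stage-1 output is invariant to positive rescaling of
any template and stage-2 betas are in units of signal per unit-variance
regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .templates import MolecularTemplate

__all__ = [
    "MaskedBold",
    "SubjectTimeSeriesSet",
    "EnrichedFCMaps",
    "mask_bold",
    "react_step1",
    "react_step2",
    "react",
]

_COND_WARN = 1e6


@dataclass
class MaskedBold:
    """BOLD data restricted to an analysis mask.

    ``data`` is ``(V, T)``; ``mask`` maps the V rows back onto the 3D
    grid; ``tr_seconds`` is the repetition time.
    """

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float = 1.1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be (V, T)")
        if self.data.shape[0] != int(self.mask.sum()):
            raise ValueError("row count must equal analysis-mask size")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def unmask(self, values: np.ndarray) -> np.ndarray:
        """Scatter a length-V vector back into a 3D volume (zeros outside)."""
        out = np.zeros(self.mask.shape, dtype=float)
        out[self.mask] = values
        return out


@dataclass
class SubjectTimeSeriesSet:
    """Stage-1 output: one time series per molecular system, ``(T, K)``."""

    series: np.ndarray
    system_names: list[str]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != len(self.system_names):
            raise ValueError("series must be (T, K) with K matching system_names")


@dataclass
class EnrichedFCMaps:
    """Stage-2 output: one beta map per system on the mask, ``(V, K)``."""

    betas: np.ndarray
    system_names: list[str]
    mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape[1] != len(self.system_names):
            raise ValueError("betas must be (V, K) with K matching system_names")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("beta maps contain non-finite values")

    def volume(self, system: str | int) -> np.ndarray:
        k = system if isinstance(system, int) else self.system_names.index(system)
        out = np.zeros(self.mask.shape, dtype=float)
        out[self.mask] = self.betas[:, k]
        return out


def mask_bold(
    bold4d: np.ndarray, mask: np.ndarray, tr_seconds: float = 1.1
) -> MaskedBold:
    """Restrict a 4D volume to an analysis mask, giving a ``(V, T)`` matrix."""
    bold4d = np.asarray(bold4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if bold4d.ndim != 4 or bold4d.shape[:3] != mask.shape:
        raise ValueError("bold must be 4D on the same grid as mask")
    return MaskedBold(data=bold4d[mask], mask=mask, tr_seconds=tr_seconds)


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant regressor column cannot be normalized")
    return (X - mu) / sd


def _template_matrix(
    bold: MaskedBold,
    templates: list[MolecularTemplate] | np.ndarray,
    strict_intersection: bool,
) -> tuple[np.ndarray, list[str]]:
    """Stack template values on the bold mask, as V x K columns.

    Default behaviour is a union grid with per-template zero fill:
    voxels excised from one template (e.g. its reference region) enter
    that regressor as zeros but stay in the analysis for the others.
    ``strict_intersection`` instead requires every template's mask to
    cover the bold mask.
    """
    if isinstance(templates, np.ndarray):
        M = np.asarray(templates, dtype=float)
        if M.ndim != 2 or M.shape[0] != bold.n_voxels:
            raise ValueError("template array must be (V, K) on the bold mask")
        return M, [f"system_{k}" for k in range(M.shape[1])]
    cols, names = [], []
    for tpl in templates:
        if tpl.values.shape != bold.mask.shape:
            raise ValueError(f"template {tpl.system_name!r} grid mismatch")
        if strict_intersection and not np.all(tpl.analysis_mask[bold.mask]):
            raise ValueError(
                f"template {tpl.system_name!r} does not cover the bold mask "
                "(strict intersection mode)"
            )
        cols.append(tpl.values[bold.mask])
        names.append(tpl.system_name)
    return np.column_stack(cols), names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T) if X.shape[1] > 2 else np.array([[1.0]])
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append(f"corr({names[i]},{names[j]})={corr[i, j]:+.3f}")
        raise ValueError("rank-deficient regressor set; " + "; ".join(pairs))
    cond = np.linalg.cond(X)
    if cond > _COND_WARN:
        warnings.warn(
            f"design condition number {cond:.3g} exceeds {_COND_WARN:.0e}",
            RuntimeWarning,
            stacklevel=3,
        )


def react_step1(
    bold: MaskedBold,
    templates: list[MolecularTemplate] | np.ndarray,
    strict_intersection: bool = False,
) -> SubjectTimeSeriesSet:
    """Spatial regression: estimate each system's dominant time series.

    For each timepoint the demeaned volume is regressed on the demeaned,
    unit-variance templates (plus intercept); the K coefficients over
    time form the ``(T, K)`` output.
    """
    M, names = _template_matrix(bold, templates, strict_intersection)
    Z = _zscore_cols(M)
    X = np.column_stack([np.ones(bold.n_voxels), Z])
    _check_design(X, names)
    Y = bold.data - bold.data.mean(axis=0, keepdims=True)  # demean each volume
    coeffs, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (K+1, T)
    return SubjectTimeSeriesSet(series=coeffs[1:].T, system_names=names)


def react_step2(bold: MaskedBold, ts: SubjectTimeSeriesSet) -> EnrichedFCMaps:
    """Temporal regression: map each system's series to a voxelwise beta map."""
    if ts.series.shape[0] != bold.n_timepoints:
        raise ValueError("time-series length must match the bold data")
    Z = _zscore_cols(ts.series)
    X = np.column_stack([np.ones(bold.n_timepoints), Z])
    _check_design(X, ts.system_names)
    Y = bold.data - bold.data.mean(axis=1, keepdims=True)  # demean each voxel
    coeffs, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (K+1, V)
    return EnrichedFCMaps(
        betas=coeffs[1:].T, system_names=list(ts.system_names), mask=bold.mask
    )


def react(
    bold: MaskedBold,
    templates: list[MolecularTemplate] | np.ndarray,
    strict_intersection: bool = False,
) -> tuple[EnrichedFCMaps, SubjectTimeSeriesSet]:
    """Run both stages; returns the beta maps and the intermediate series."""
    ts = react_step1(bold, templates, strict_intersection=strict_intersection)
    return react_step2(bold, ts), ts
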