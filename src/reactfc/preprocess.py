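"""Denoising of motion/distortion-corrected, standard-space rs-fMRI.

Covers the stages applied after registration: confound (nuisance)
regression, motion-spike regressors from framewise displacement (FD),
discrete-cosine high-pass filtering, Gaussian spatial smoothing, and a
mean-FD quality-control gate. Upstream stages (slice timing, distortion
and motion correction, anatomical processing) are assumed done by
external tools.

Conventions
-----------
* 4D data are arrays of shape ``(nx, ny, nz, T)``; 2D ``(V, T)``
  matrices are accepted everywhere time-domain operations apply.
* Motion parameters are ``(T, 6)``: three translations in mm followed
  by three rotations in radians.
* FD uses backward differences with rotations converted to arc length
  on a 50 mm sphere (the dominant convention).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "framewise_displacement",
    "spike_regressors",
    "nuisance_regression",
    "highpass_filter",
    "gaussian_smooth",
    "qc_mean_fd",
    "mean_signal",
]


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Per-frame head displacement in mm (Power-style backward differences).

    ``FD_t = sum |d translations| + r * sum |d rotations|`` with the first
    frame fixed at 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (T, 6); got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least two frames to compute FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def spike_regressors(fd: np.ndarray, threshold_mm: float = 0.4) -> np.ndarray:
    """One-hot scrub regressors for frames with FD above threshold.

    Returns a ``(T, n_spikes)`` indicator matrix; empty second axis when
    no frame exceeds the threshold.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1:
        raise ValueError("fd must be 1D")
    if np.any(fd < 0):
        raise ValueError("FD values must be nonnegative")
    flagged = np.flatnonzero(fd > threshold_mm)
    out = np.zeros((fd.size, flagged.size))
    out[flagged, np.arange(flagged.size)] = 1.0
    return out


def _as_matrix(bold: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Flatten 4D bold to (V, T); pass 2D through."""
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 4:
        shape = bold.shape
        return bold.reshape(-1, shape[-1]), shape
    if bold.ndim == 2:
        return bold, bold.shape
    raise ValueError(f"expected 2D (V, T) or 4D (x, y, z, T) data; got {bold.ndim}D")


def _name_collinear(X: np.ndarray, names: list[str]) -> str:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    bad = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-10:
                bad.append(f"{names[i]}~{names[j]}")
    return ", ".join(bad) if bad else "unidentified columns"


def nuisance_regression(bold: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize each voxel's series against confounds plus an intercept.

    Residuals are exactly orthogonal to every confound column. A
    rank-deficient confound matrix raises, naming collinear pairs.
    """
    Y, shape = _as_matrix(bold)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != Y.shape[1]:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, expected T={Y.shape[1]}"
        )
    T = Y.shape[1]
    X = np.column_stack([np.ones(T), confounds])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ["intercept"] + [f"confound_{i}" for i in range(confounds.shape[1])]
        raise ValueError(
            "confound matrix is rank deficient (collinear: "
            f"{_name_collinear(X, names)})"
        )
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    out = resid.T
    return out.reshape(shape) if len(shape) == 4 else out


def _dct_basis(T: int, n: int) -> np.ndarray:
    """First ``n`` non-constant DCT-II drift regressors of length T."""
    t = np.arange(T)
    return np.column_stack(
        [np.cos(np.pi * (t + 0.5) * j / T) for j in range(1, n + 1)]
    )


def highpass_filter(
    bold: np.ndarray, tr_seconds: float, cutoff_hz: float = 1.0 / 128
) -> np.ndarray:
    """Remove slow drift below ``cutoff_hz`` via a discrete-cosine basis.

    The drift span comprises the constant plus the first
    ``floor(2 * T * tr * cutoff) + 1`` cosine regressors; projecting it
    out is idempotent.
    """
    Y, shape = _as_matrix(bold)
    T = Y.shape[1]
    if T < 8:
        raise ValueError("need at least 8 timepoints")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at/above Nyquist {nyquist} Hz")
    n = int(np.floor(2 * T * tr_seconds * cutoff_hz)) + 1
    X = np.column_stack([np.ones(T), _dct_basis(T, n)])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = (Y.T - X @ beta).T
    return resid.reshape(shape) if len(shape) == 4 else resid


def gaussian_smooth(
    bold: np.ndarray,
    fwhm_mm: float = 5.0,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> np.ndarray:
    """Volume-wise isotropic Gaussian smoothing.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, in voxel units. Edges
    are handled by kernel renormalization (division by the smoothed
    all-ones volume) so a constant image is exactly preserved and each
    frame's mean is conserved to numerical precision.
    """
    bold = np.asarray(bold, dtype=float)
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
        raise ValueError("voxel_size_mm must be 3 positive values")
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_size
    single = bold.ndim == 3
    if single:
        bold = bold[..., None]
    if bold.ndim != 4:
        raise ValueError("expected 3D or 4D data")
    norm = ndimage.gaussian_filter(
        np.ones(bold.shape[:3]), sigma=sigma_vox, mode="constant"
    )
    out = np.empty_like(bold)
    for t in range(bold.shape[-1]):
        out[..., t] = (
            ndimage.gaussian_filter(bold[..., t], sigma=sigma_vox, mode="constant")
            / norm
        )
    return out[..., 0] if single else out


def qc_mean_fd(fd: np.ndarray, bound_mm: float = 0.3) -> tuple[bool, float]:
    """Mean-FD quality gate: returns ``(mean < bound, mean)``."""
    fd = np.asarray(fd, dtype=float)
    mean = float(fd.mean())
    return mean < bound_mm, mean


def mean_signal(bold: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Average time series over a tissue mask (e.g. CSF or white matter)."""
    bold = np.asarray(bold, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if bold.ndim != 4 or bold.shape[:3] != mask.shape:
        raise ValueError("bold must be 4D on the same grid as mask")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    return bold[mask].mean(axis=0)
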