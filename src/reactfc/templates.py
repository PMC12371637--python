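"""Preparation of molecular density templates.

A molecular template is a 3D density map of a neurotransmitter system
(e.g. DAT, NET, SERT or mGluR5 from PET/SPECT averages of healthy
controls). Before it can serve as a spatial regressor it is restricted
to grey matter, the kinetic-model reference region (whose density is by
construction uninformative) is excised, and the surviving values are
min-max rescaled to [0, 1].

The fixed order is: grey-matter masking, reference-region excision, then
rescaling on the surviving voxels — so that excluded extremes cannot
distort the [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularTemplate",
    "rescale01",
    "apply_gm_mask",
    "exclude_reference_region",
    "prepare_template",
]


@dataclass
class MolecularTemplate:
    """A prepared molecular density map for one neurotransmitter system.

    Attributes
    ----------
    values : ndarray
        3D map, min-max rescaled to [0, 1] inside ``analysis_mask`` and
        exactly zero outside it.
    system_name : str
        Label of the molecular system (e.g. ``"NET"``).
    analysis_mask : ndarray of bool
        Voxels where the template is defined.
    reference_region : ndarray of bool
        Voxels excised because they served as the kinetic-model
        reference region; disjoint from ``analysis_mask``.
    """

    values: np.ndarray
    system_name: str
    analysis_mask: np.ndarray
    reference_region: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reference_region is None:
            self.reference_region = np.zeros(self.values.shape, dtype=bool)
        if self.values.shape != self.analysis_mask.shape:
            raise ValueError("values and analysis_mask must share a grid")
        if np.any(self.analysis_mask & self.reference_region):
            raise ValueError("reference_region must be disjoint from analysis_mask")


def _check_same_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"grid mismatch: {what} has shape {b.shape}, expected {a.shape}; "
            "all inputs must live on the same voxel grid (no resampling is "
            "performed)"
        )


def rescale01(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale ``volume`` to [0, 1] within ``mask``; zero outside.

    Raises
    ------
    ValueError
        If the mask is empty, contains non-finite values, or the map is
        constant within the mask (degenerate rescaling).
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_same_grid(volume, mask, "mask")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = volume[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values inside mask")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("degenerate map: constant within mask, cannot rescale")
    out = np.zeros_like(volume)
    out[mask] = (vals - lo) / (hi - lo)
    return out


def apply_gm_mask(
    volume: np.ndarray, gm_prob: np.ndarray, threshold: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a map to grey matter.

    Voxels with grey-matter probability strictly above ``threshold`` are
    retained; all others are zeroed.

    Returns
    -------
    mask : ndarray of bool
        The retained voxels.
    masked : ndarray
        The map with non-grey-matter voxels zeroed.
    """
    volume = np.asarray(volume, dtype=float)
    gm_prob = np.asarray(gm_prob, dtype=float)
    _check_same_grid(volume, gm_prob, "gm_prob")
    if gm_prob.min() < 0 or gm_prob.max() > 1:
        raise ValueError("gm_prob must be a probability map in [0, 1]")
    mask = gm_prob > threshold
    masked = np.where(mask, volume, 0.0)
    return mask, masked


def exclude_reference_region(
    volume: np.ndarray, analysis_mask: np.ndarray, region: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Excise a reference region from a map and its analysis mask.

    Returns the updated ``(mask, masked_volume)``. An empty region is a
    no-op; a region covering the whole mask is an error.
    """
    volume = np.asarray(volume, dtype=float)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    region = np.asarray(region, dtype=bool)
    _check_same_grid(volume, region, "region")
    _check_same_grid(volume, analysis_mask, "analysis_mask")
    new_mask = analysis_mask & ~region
    if analysis_mask.any() and not new_mask.any():
        raise ValueError("reference region covers the entire analysis mask")
    return new_mask, np.where(new_mask, volume, 0.0)


def prepare_template(
    raw: np.ndarray,
    gm_prob: np.ndarray,
    region: np.ndarray | None,
    system_name: str,
    gm_threshold: float = 0.3,
) -> MolecularTemplate:
    """Full preparation: GM mask -> reference excision -> [0, 1] rescale."""
    gm_mask, masked = apply_gm_mask(raw, gm_prob, gm_threshold)
    if region is None:
        region = np.zeros(np.shape(raw), dtype=bool)
    else:
        region = np.asarray(region, dtype=bool)
    mask, masked = exclude_reference_region(masked, gm_mask, region)
    values = rescale01(masked, mask)
    return MolecularTemplate(
        values=values,
        system_name=system_name,
        analysis_mask=mask,
        reference_region=region & gm_mask,
    )
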