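"""Labeling significant clusters against atlas parcellations.

Significant voxel clusters are described by their normalized overlap
with a label atlas (functional networks or anatomical regions): the
percentage of the atlas-covered part of the cluster falling inside each
label. Cluster-mean enriched-FC values per subject serve as effect-size
inputs (e.g. for partial correlations with symptom scores) — never for
inference, which would be circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtlasLabelVolume",
    "normalized_overlap",
    "top_regions",
    "extract_cluster_mean",
]


@dataclass
class AtlasLabelVolume:
    """Integer label volume plus a label -> name table (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @classmethod
    def from_table(cls, labels: np.ndarray, table: pd.DataFrame) -> "AtlasLabelVolume":
        """Build from a TSV-style table with ``label`` and ``name`` columns."""
        return cls(labels=labels, names=dict(zip(table["label"], table["name"])))


def normalized_overlap(
    sig_mask: np.ndarray,
    atlas: AtlasLabelVolume,
    denominator: str = "cluster",
) -> pd.DataFrame:
    """Percentage overlap of a significant-voxel mask with atlas labels.

    With the default ``denominator="cluster"`` each label's percentage
    is ``100 * |sig ∩ label| / |sig ∩ atlas coverage|``, so percentages
    sum to 100 over labels; ``denominator="region"`` instead normalizes
    by each label's own size. Rows are sorted by descending percentage,
    ties broken by name.
    """
    sig = np.asarray(sig_mask, dtype=bool)
    if sig.shape != atlas.labels.shape:
        raise ValueError("mask and atlas must share a grid")
    if not sig.any():
        raise ValueError("significant mask is empty")
    covered = sig & (atlas.labels > 0)
    if not covered.any():
        raise ValueError("cluster does not intersect atlas coverage")
    if denominator not in ("cluster", "region"):
        raise ValueError("denominator must be 'cluster' or 'region'")
    rows = []
    inter = np.bincount(atlas.labels[covered].ravel())
    for label, name in atlas.names.items():
        n_inter = int(inter[label]) if label < inter.size else 0
        if denominator == "cluster":
            pct = 100.0 * n_inter / covered.sum()
        else:
            pct = 100.0 * n_inter / max(int((atlas.labels == label).sum()), 1)
        rows.append({"label": label, "name": name, "n_voxels": n_inter, "percent": pct})
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["percent", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def top_regions(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """First k rows by percentage (ties by name); all rows when k exceeds them."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = table.sort_values(
        ["percent", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ordered.head(k)


def extract_cluster_mean(stack: np.ndarray, sig_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean map value within a cluster mask.

    ``stack`` is ``(N, nx, ny, nz)``; the return is length N. Linear in
    the input maps.
    """
    stack = np.asarray(stack, dtype=float)
    sig = np.asarray(sig_mask, dtype=bool)
    if stack.ndim != 4 or stack.shape[1:] != sig.shape:
        raise ValueError("stack must be (N, nx, ny, nz) on the mask grid")
    if not sig.any():
        raise ValueError("cluster mask is empty")
    return stack[:, sig].mean(axis=1)
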