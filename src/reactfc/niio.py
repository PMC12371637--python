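"""Thin NIfTI / text I/O wrappers used by the command-line interface."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_volume(
    path: str | Path, data: np.ndarray, voxel_size_mm: float = 2.0
) -> None:
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def load_mask(path: str | Path) -> np.ndarray:
    return load_volume(path) > 0.5


def load_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(str(path))
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 whitespace-separated columns")
    return motion


def save_motion(path: str | Path, motion: np.ndarray) -> None:
    np.savetxt(str(path), motion, fmt="%.8f")


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(str(path), sep="\t", index=False)
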