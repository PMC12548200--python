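"""NIfTI input/output helpers (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid

__all__ = ["save_volume", "load_volume", "save_field", "load_field"]


def save_volume(path: str | Path, values: np.ndarray, grid: Grid) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    aff = img.affine
    diag = np.diag(aff)[:3]
    if not np.allclose(aff[:3, :3], np.diag(diag), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal) affines are supported")
    data = np.asarray(img.dataobj, dtype=float)
    origin = aff[:3, 3].copy()
    # fold negative axis conventions into positive spacing with a shifted origin
    for ax in range(3):
        if diag[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = aff[ax, 3] + diag[ax] * (data.shape[ax] - 1)
    grid = Grid(shape=data.shape[:3], spacing=tuple(np.abs(diag)), origin=tuple(origin))
    return data, grid


def save_field(path: str | Path, vectors: np.ndarray, grid: Grid) -> None:
    """Save a displacement field (x, y, z, 3) in mm as a 4-D vector NIfTI."""
    vectors = np.asarray(vectors, dtype=np.float32)
    if vectors.shape != tuple(grid.shape) + (3,):
        raise ValueError(f"field shape {vectors.shape} does not match grid {grid.shape}")
    nib.save(nib.Nifti1Image(vectors, grid.affine), str(path))


def load_field(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 4-D (x,y,z,3) vector image")
    aff = img.affine
    diag = np.diag(aff)[:3]
    if not np.allclose(aff[:3, :3], np.diag(diag), atol=1e-6) or np.any(diag <= 0):
        raise ValueError(f"{path}: only positive diagonal affines are supported for fields")
    grid = Grid(shape=data.shape[:3], spacing=tuple(diag), origin=tuple(aff[:3, 3]))
    return data, grid
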