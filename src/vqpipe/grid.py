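"""Image grid geometry and the basic volume container.

All volumes in the pipeline live on axis-aligned grids: RAS-like world axes,
voxel centers at ``index * spacing + origin`` (mm), 0-based indices.  By
convention axis 0 runs right->left, axis 1 ventral->dorsal and axis 2
caudal->cranial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "CTVolume"]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned sampling grid in world millimetres."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel->world map (diagonal; NIfTI convention)."""
        a = np.diag(list(self.spacing) + [1.0])
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def matches(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def meshgrid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, one array per axis."""
        axes = [
            np.arange(n) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class CTVolume:
    """A scalar CT volume in Hounsfield units."""

    hu: np.ndarray
    grid: Grid
    phase: str | None = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.shape != tuple(self.grid.shape):
            raise ValueError(
                f"volume shape {self.hu.shape} does not match grid {self.grid.shape}"
            )


def require_same_grid(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.matches(g):
            raise ValueError(f"grids differ: {first} vs {g}")
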