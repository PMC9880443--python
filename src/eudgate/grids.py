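"""Regular-grid containers for doses, structure masks and displacement fields.

Axis convention used throughout the package: arrays are stored in index order
``(z, y, x)`` where z is the cranio-caudal axis, y anterior-posterior and
x left-right.  All 3-vectors (points, spacings, displacement components,
per-axis statistics) follow the same ``(z, y, x)`` order.  The world
coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
(voxel-center convention), in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GridSpec",
    "DoseGrid",
    "StructureMask",
    "DisplacementField",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, ``(nz, ny, nx)``.
    spacing : tuple of float
        Voxel spacing in mm per axis.
    origin : tuple of float
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world points (mm) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask.

        Returns an ``(n, 3)`` array in C (lowest-linear-index-first) order.
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)


def _check_same_grid(a: "GriddedData", b: "GriddedData") -> None:
    if a.grid != b.grid:
        raise ValueError(
            f"grid mismatch: {a.grid} vs {b.grid} — all volumes of a series "
            "must share shape, spacing and origin"
        )


@dataclass
class GriddedData:
    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[:3] != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )


@dataclass
class DoseGrid(GriddedData):
    """Scalar dose per voxel (Gy, or fraction of prescription when normalized)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float, copy=False)
        if self.values.ndim != 3:
            raise ValueError("dose must be a scalar 3-D volume")

    def sample(self, points_mm: np.ndarray, order: int = 1) -> np.ndarray:
        """Trilinear (order=1) sample at world points; clamps to the boundary."""
        idx = self.grid.world_to_index(np.atleast_2d(points_mm))
        return map_coordinates(self.values, idx.T, order=order, mode="nearest")


@dataclass
class StructureMask(GriddedData):
    """Boolean voxel set (CTV, PTV, ROI) on a regular grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(bool, copy=False)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3-D volume")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class DisplacementField(GriddedData):
    """Per-voxel displacement (mm), mapping planning geometry to a fraction's.

    ``values`` has shape ``(nz, ny, nx, 3)`` with components in (z, y, x)
    order.  A tissue element at planning point ``q`` sits at ``q + u(q)``
    during the fraction.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float, copy=False)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise ValueError("field must have shape (nz, ny, nx, 3)")

    def sample(self, points_mm: np.ndarray, order: int = 1) -> np.ndarray:
        """Trilinearly interpolated displacement vectors at world points."""
        idx = self.grid.world_to_index(np.atleast_2d(points_mm))
        out = np.empty((idx.shape[0], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.values[..., c], idx.T, order=order, mode="nearest"
            )
        return out

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.values**2).sum(axis=-1)).max())
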