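"""Shared domain types: grid geometry, volumes, series, displacement fields, ROIs.

All world coordinates and displacements are in physical millimetres; voxel
indices are 0-based and refer to voxel centres, so the world position of
index ``i`` along an axis is ``origin + i * spacing``.  Intensities are in
Hounsfield units (HU) stored as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "PerfusionSeries",
    "DisplacementField",
    "ROIMask",
    "sample_volume",
    "mask_from_sphere",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3D voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be 3-tuples")
        if any(n < 2 for n in shape):
            raise ValueError(f"all grid dimensions must be >= 2, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the lattice bounding box (centre-to-centre)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centres as three broadcastable axes."""
        axes = [
            o + np.arange(n) * s
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def _check_same_grid(*grids: VolumeGrid) -> VolumeGrid:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError(f"grid mismatch: {g} != {first}")
    return first


@dataclass
class ScalarVolume:
    """A single 3D CT volume (one time frame) in HU on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class PerfusionSeries:
    """Ordered, co-registered dynamic series: one ScalarVolume per time point."""

    frames: list[ScalarVolume]
    times_s: np.ndarray

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1 or len(self.times_s) != len(self.frames):
            raise ValueError("times_s must have one entry per frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        _check_same_grid(*(f.grid for f in self.frames))

    @property
    def grid(self) -> VolumeGrid:
        return self.frames[0].grid

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack to a 4D array with time as the last axis."""
        return np.stack([f.values for f in self.frames], axis=-1)

    @classmethod
    def from_array(
        cls, grid: VolumeGrid, data: np.ndarray, times_s: np.ndarray
    ) -> "PerfusionSeries":
        data = np.asarray(data, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected 4D array with time as the last axis")
        frames = [ScalarVolume(grid, data[..., t]) for t in range(data.shape[-1])]
        return cls(frames, times_s)


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in physical mm, shape (nx, ny, nz, 3)."""

    grid: VolumeGrid
    vectors: np.ndarray
    _bounded: bool = True  # internal: vector fields (forces, raw solver
    # output) reuse this container without the physical magnitude bound

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vectors shape {self.vectors.shape} != {self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        if self._bounded:
            bound = float(np.linalg.norm(self.grid.extent_mm)) + float(
                np.max(self.grid.spacing)
            )
            max_mag = float(np.max(np.linalg.norm(self.vectors, axis=-1), initial=0.0))
            if max_mag > bound:
                raise ValueError(
                    f"displacement magnitude {max_mag:.1f} mm exceeds volume extent"
                )

    @classmethod
    def zero(cls, grid: VolumeGrid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    @classmethod
    def unchecked(cls, grid: VolumeGrid, vectors: np.ndarray) -> "DisplacementField":
        """Vector field on a grid without the displacement magnitude bound."""
        return cls(grid, vectors, _bounded=False)

    def max_magnitude_mm(self) -> float:
        return float(np.max(np.linalg.norm(self.vectors, axis=-1)))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.vectors.copy())


@dataclass
class ROIMask:
    """Boolean region-of-interest on a grid; ``label`` names the tissue."""

    grid: VolumeGrid
    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        if not self.mask.any():
            raise ValueError(f"ROI '{self.label}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def sample_volume(
    volume: ScalarVolume,
    points: np.ndarray,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Sample a volume at world-space points (mm), returning HU values.

    Trilinear sampling is exact at lattice points; out-of-domain points
    clamp to the nearest edge value (matching the Neumann boundary
    treatment used by the registration PDE).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[None, :]
    if points.shape[-1] != 3:
        raise ValueError("points must be (..., 3) world mm coordinates")
    if not np.all(np.isfinite(points)):
        raise ValueError("sample points must be finite")
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    idx = volume.grid.world_to_index(points)
    order = 1 if interpolation == "trilinear" else 0
    return ndimage.map_coordinates(
        volume.values, idx.reshape(-1, 3).T, order=order, mode="nearest"
    ).reshape(points.shape[:-1])


def mask_from_sphere(
    grid: VolumeGrid,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    label: str = "sphere",
) -> ROIMask:
    """Spherical ROI: voxels whose centres lie within ``radius_mm`` of the centre.

    A reproducible stand-in for the manually placed circular ROIs of
    perfusion reading practice.
    """
    if radius_mm <= 0:
        raise ValueError("sphere radius must be > 0 mm")
    x, y, z = grid.voxel_centers()
    cx, cy, cz = (float(c) for c in center_mm)
    dist2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    mask = dist2 <= radius_mm**2
    if not mask.any():
        raise ValueError("empty ROI: sphere lies entirely outside the grid")
    return ROIMask(grid, mask, label)
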