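"""Voxel-grid containers shared by every stage of the pipeline.

A :class:`VoxelGrid` is a 3D scalar field (PET in SUV units, MR in arbitrary
intensity) with per-axis voxel spacing and an origin offset, both in
millimetres.  A :class:`ROIMask` is a binary grid aligned to a paired
``VoxelGrid``.  Arrays are indexed ``(x, y, z)``; axial slices are
``values[:, :, k]`` and all in-plane texture directions live in the first two
axes.  Voxel centres sit at ``origin + (index + 0.5) * spacing`` (half-open
extent convention), which makes resampling shape arithmetic unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ROIMask"]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(spacing))
    if len(s) == 1:
        s = (s[0], s[0], s[0])
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {s}")
    if any(v <= 0 or not np.isfinite(v) for v in s):
        raise ValueError(f"spacing must be positive and finite, got {s}")
    return s


@dataclass
class VoxelGrid:
    """A 3D scalar volume with spacing/origin metadata (mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (shape * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def copy_with(self, values: np.ndarray, spacing_mm=None) -> "VoxelGrid":
        return VoxelGrid(
            values,
            spacing_mm=self.spacing_mm if spacing_mm is None else spacing_mm,
            origin_mm=self.origin_mm,
        )


@dataclass
class ROIMask:
    """Binary lesion mask aligned to a :class:`VoxelGrid`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    require_nonempty: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.values = arr.astype(bool)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if self.require_nonempty and not self.values.any():
            raise ValueError("lesion mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, grid: VoxelGrid) -> None:
        """Raise if this mask is not on the same lattice as ``grid``."""
        if self.shape != grid.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {grid.shape}"
            )
        if not np.allclose(self.spacing_mm, grid.spacing_mm):
            raise ValueError(
                f"mask spacing {self.spacing_mm} does not match volume "
                f"spacing {grid.spacing_mm}"
            )

    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        """Per-axis half-open index bounds ``((lo, hi), ...)`` of set voxels."""
        idx = np.nonzero(self.values)
        return tuple((int(ax.min()), int(ax.max()) + 1) for ax in idx)
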