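"""PET metabolic parameters: SUV conversion, 40 %-of-SUVmax delineation,
and the SUVmax / SUVmean / MTV / TLG summary.

The metabolic region of interest is found inside an operator-style seed box:
the maximum SUV in the box sets a relative threshold (default 40 %), voxels
at or above the threshold are kept, and the result is restricted to the
26-connected component containing the maximum voxel — a deterministic
stand-in for the manual exclusion of nearby physiologic uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ROIMask, VoxelGrid

__all__ = ["SeedBox", "MetabolicSummary", "compute_suv",
           "delineate_metabolic_roi", "metabolic_summary", "box_from_mask"]


@dataclass(frozen=True)
class SeedBox:
    """Axis-aligned half-open voxel-index bounds ``((lo, hi), ...)`` per axis."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)

    def validate(self, shape: tuple[int, int, int]) -> None:
        for (lo, hi), n in zip(self.bounds, shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"seed box {self.bounds} outside grid {shape}")


@dataclass(frozen=True)
class MetabolicSummary:
    """Per-lesion metabolic parameters (SUV units, volume in mL)."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float


def box_from_mask(mask: ROIMask, dilate_voxels: int = 3) -> SeedBox:
    """Seed box from the anatomical mask's bounding box, dilated per axis."""
    bb = mask.bounding_box()
    bounds = tuple(
        (max(0, lo - dilate_voxels), min(n, hi + dilate_voxels))
        for (lo, hi), n in zip(bb, mask.shape)
    )
    return SeedBox(bounds)


def compute_suv(activity_kbq_per_ml: VoxelGrid, injected_dose_mbq: float,
                body_weight_kg: float) -> VoxelGrid:
    """Standardized uptake value from an activity-concentration volume.

    SUV = concentration / (dose / weight), assuming unit tissue density,
    which for concentration in kBq/mL, dose in MBq and weight in kg reduces
    to ``concentration * weight / dose``.
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    factor = body_weight_kg / injected_dose_mbq
    return activity_kbq_per_ml.copy_with(activity_kbq_per_ml.values * factor)


def delineate_metabolic_roi(suv: VoxelGrid, box: SeedBox,
                            threshold_fraction: float = 0.40) -> ROIMask:
    """Adaptive-threshold tumor boundary at a fraction of the in-box SUVmax.

    Returns the voxels within the box whose SUV is at least
    ``threshold_fraction * SUVmax``, restricted to the 26-connected
    component containing the maximum voxel.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError(f"threshold fraction must be in (0, 1], "
                         f"got {threshold_fraction}")
    box.validate(suv.shape)
    sub = suv.values[box.slices()]
    vmax = float(sub.max())
    if vmax == float(sub.min()):
        raise ValueError("flat seed box: SUVmax equals the box minimum, "
                         "no boundary can be delineated")
    hot = sub >= threshold_fraction * vmax
    labels, _ = ndimage.label(hot, structure=np.ones((3, 3, 3)))
    max_idx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    keep = labels == labels[max_idx]
    out = np.zeros(suv.shape, dtype=bool)
    out[box.slices()] = keep
    return ROIMask(out, spacing_mm=suv.spacing_mm, origin_mm=suv.origin_mm)


def metabolic_summary(suv: VoxelGrid, mask: ROIMask) -> MetabolicSummary:
    """SUVmax / SUVmean over the mask, MTV in mL, TLG = SUVmean x MTV."""
    mask.check_aligned(suv)
    vals = suv.values[mask.values]
    if vals.size == 0:
        raise ValueError("empty metabolic mask")
    mtv_ml = mask.voxel_count * mask.voxel_volume_mm3 / 1000.0
    suv_mean = float(vals.mean())
    return MetabolicSummary(
        suv_max=float(vals.max()),
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg=suv_mean * mtv_ml,
    )
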