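"""Image preprocessing: isotropic resampling and 0-255 grey normalization.

Both PET and MR volumes are resampled to a common 1 mm isotropic lattice
(trilinear for images, nearest-neighbour for masks) and then linearly
rescaled so the volume minimum maps to grey level 0 and the maximum to 255.
Texture features are computed on the normalized volumes; metabolic
parameters are computed on the resampled but *un-normalized* SUV volume.

Grid convention: output voxel centres sit at ``origin + (k + 0.5) * target``
and the output shape is ``ceil(extent / target)`` per axis, so the physical
extent is preserved up to one voxel of padding.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage

from .grids import ROIMask, VoxelGrid

__all__ = ["resample_isotropic", "resample_mask", "normalize_grey"]

log = logging.getLogger(__name__)


def _resample_values(values: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    new_shape = tuple(
        max(1, math.ceil(n * s / target)) for n, s in zip(values.shape, spacing)
    )
    grids = [
        ((np.arange(m) + 0.5) * target) / s - 0.5
        for m, s in zip(new_shape, spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(
        values.astype(np.float32, copy=False),
        np.stack([c.astype(np.float32) for c in coords]),
        order=order,
        mode="nearest",
    )


def resample_isotropic(volume: VoxelGrid, target_spacing_mm: float = 1.0,
                       mode: str = "linear") -> VoxelGrid:
    """Resample a volume to an isotropic lattice.

    Parameters
    ----------
    volume:
        Input grid at arbitrary (anisotropic) spacing.
    target_spacing_mm:
        Edge length of the output voxels; default 1 mm.
    mode:
        ``"linear"`` (trilinear interpolation, for images) or ``"nearest"``
        (for label volumes; preserves the value alphabet).
    """
    if target_spacing_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    order = 1 if mode == "linear" else 0
    out = _resample_values(volume.values, volume.spacing_mm,
                           float(target_spacing_mm), order)
    return VoxelGrid(out, spacing_mm=(target_spacing_mm,) * 3,
                     origin_mm=volume.origin_mm)


def resample_mask(mask: ROIMask, target_spacing_mm: float = 1.0) -> ROIMask:
    """Nearest-neighbour resampling for binary masks."""
    if target_spacing_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    out = _resample_values(mask.values.astype(np.float32), mask.spacing_mm,
                           float(target_spacing_mm), order=0)
    return ROIMask(out > 0.5, spacing_mm=(target_spacing_mm,) * 3,
                   origin_mm=mask.origin_mm)


def normalize_grey(volume: VoxelGrid) -> VoxelGrid:
    """Linearly rescale intensities to integer grey levels 0-255.

    The volume minimum maps to 0 and the maximum to 255; intermediate values
    are converted linearly and rounded half away from zero.  Statistics are
    taken over the whole volume, not the ROI, so within-lesion minima remain
    informative (``MinIntensity``).  A constant volume maps to all zeros with
    a warning.
    """
    vals = np.asarray(volume.values, dtype=np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        log.warning("normalize_grey: constant volume (value %g); output all 0", lo)
        return volume.copy_with(np.zeros(volume.shape, dtype=np.int16))
    scaled = 255.0 * (vals - lo) / (hi - lo)
    # round half away from zero (values are nonnegative here)
    out = np.floor(scaled + 0.5).astype(np.int16)
    return volume.copy_with(out)
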