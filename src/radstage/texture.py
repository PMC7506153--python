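"""Radiomic texture catalog: histogram, shape, Haralick, GLCM and RLM features.

The catalog holds exactly 396 named features per modality:

* 42 histogram statistics of the masked intensities,
* 9 shape factors of the binary lesion mask,
* 21 Haralick features (7 bases x 3 offsets, on the direction-averaged GLCM),
* 126 grey-level co-occurrence features (7 bases x 3 offsets x 6 direction
  variants), and
* 198 run-length features (11 bases x 3 steps x 6 direction variants).

Directions are the four 2D in-plane angles (0/45/90/135 degrees) inside each
axial slice, accumulated over slices; per base feature and offset the six
variants are the four per-angle values, their mean (``AllDirection``) and
their population standard deviation (``AllDirection_SD``).  Co-occurrence
matrices are symmetrized and normalized to pair probabilities.  The run-length
"step" is the scan-lattice stride: runs are counted on every step-th voxel
along the direction, so a step of 1 is the classical GLRLM.

Grey-level conventions: :func:`discretize` bins masked intensities into
``L`` equal-width levels ``0..L-1``.  GLCM features are computed with matrix
indices ``1..L`` (only moment features depend on the choice).  Run-emphasis
features use the *stored* grey value as the level index ``i`` and reject
level 0, so the extraction pipeline feeds the RLM branch 1-based levels
(``discretize(...) + 1``); this keeps ``1/i**2`` emphases finite and makes
hand-enumerated tables read literally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, distance

from .grids import ROIMask, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "GreyVolume", "CooccurrenceMatrix", "RunLengthTable", "NoPairsError",
    "discretize", "glcm", "glcm_energy", "glcm_entropy", "glcm_feature_set",
    "rlm", "rlm_feature_set", "haralick_features", "histogram_features",
    "shape_features", "direction_variants", "build_catalog", "extract_all",
    "DIRECTIONS", "OFFSETS", "GLCM_BASES", "RLM_BASES", "HARALICK_BASES",
]

#: in-plane step (axis0, axis1) per named direction
DIRECTIONS: dict[str, tuple[int, int]] = {
    "angle0": (0, 1),
    "angle45": (1, 1),
    "angle90": (1, 0),
    "angle135": (1, -1),
}
OFFSETS: tuple[int, ...] = (1, 4, 7)

GLCM_BASES = [
    "GLCMEnergy", "GLCMEntropy", "GLCMContrast", "GLCMCorrelation",
    "GLCMInverseDifferenceMoment", "GLCMClusterShade", "GLCMClusterProminence",
]
RLM_BASES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GreyLevelNonuniformity",
    "RunLengthNonuniformity", "RunPercentage", "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis", "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis", "LongRunLowGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
]
HARALICK_BASES = [
    "HaralickSumAverage", "HaralickSumEntropy", "HaralickDifferenceEntropy",
    "HaralickIMC1", "HaralickIMC2", "HaralickAutocorrelation",
    "HaralickDissimilarity",
]
HISTOGRAM_NAMES = [
    "MinIntensity", "MaxIntensity", "RangeIntensity", "MeanIntensity",
    "MedianIntensity", "ModeIntensity", "StandardDeviation", "Variance",
    "MeanAbsoluteDeviation", "MedianAbsoluteDeviation", "Skewness", "Kurtosis",
    "Energy", "RootMeanSquare", "HistogramEntropy", "Uniformity",
    "CoefficientOfVariation", "InterquartileRange", "QuartileDispersion",
    "Percentile01", "Percentile99", "Percentile99Minus01", "MeanTopDecile",
] + [f"Percentile{p:02d}" for p in range(5, 100, 5)]
SHAPE_NAMES = [
    "Volume", "SurfaceArea", "SurfaceToVolumeRatio", "Sphericity",
    "Compactness1", "Compactness2", "SphericalDisproportion",
    "Maximum3DDiameter", "Elongation",
]

_DIR_NAMES = list(DIRECTIONS)


class NoPairsError(ValueError):
    """Raised when a direction/offset admits no in-mask voxel pair."""


@dataclass
class GreyVolume:
    """Integer grey levels with the mask and grid metadata they refer to."""

    levels: np.ndarray
    L: int
    mask: ROIMask
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.ndim != 3:
            raise ValueError("grey volume must be 3D")
        if not np.issubdtype(self.levels.dtype, np.integer):
            raise ValueError("grey levels must be integers")


@dataclass
class CooccurrenceMatrix:
    g: np.ndarray            # (L, L) pair probabilities, symmetric, sums to 1
    direction: str
    offset_voxels: int

    @property
    def L(self) -> int:
        return self.g.shape[0]


@dataclass
class RunLengthTable:
    counts: np.ndarray       # (max_level + 1, max_length); col j-1 <-> length j
    n_r: int                 # total number of runs
    direction: str
    step: int


# ---------------------------------------------------------------------------
# discretization

def discretize(volume: VoxelGrid, mask: ROIMask, L: int) -> GreyVolume:
    """Equal-width binning of the masked intensity range into ``L`` levels."""
    if L < 2:
        raise ValueError(f"need at least 2 grey levels, got {L}")
    mask.check_aligned(volume)
    if not mask.values.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume.values, dtype=np.float64)
    m = mask.values
    lo, hi = float(vals[m].min()), float(vals[m].max())
    levels = np.zeros(vals.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((vals - lo) / (hi - lo) * L).astype(np.int32)
        levels = np.clip(lv, 0, L - 1)
    return GreyVolume(levels, L=L, mask=mask, spacing_mm=volume.spacing_mm)


# ---------------------------------------------------------------------------
# grey-level co-occurrence

def _pair_slices(n: int, o: int) -> tuple[slice, slice]:
    return (slice(max(0, -o), n - max(0, o)),
            slice(max(0, o), n - max(0, -o)))


def glcm(grey: GreyVolume, direction: str, offset_voxels: int) -> CooccurrenceMatrix:
    """Symmetrized, normalized co-occurrence matrix at one direction/offset.

    Ordered voxel pairs separated by ``offset_voxels`` times the direction
    step, both inside the mask, are counted within each axial slice and
    accumulated over slices; both orderings are counted (symmetrization) and
    counts are normalized to probabilities.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    di, dj = DIRECTIONS[direction]
    oi, oj = di * offset_voxels, dj * offset_voxels
    lv, m = grey.levels, grey.mask.values
    nx, ny = lv.shape[:2]
    xa, xb = _pair_slices(nx, oi)
    ya, yb = _pair_slices(ny, oj)
    counts = np.zeros((grey.L, grey.L), dtype=np.float64)
    if xa.stop > xa.start and ya.stop > ya.start:
        both = m[xa, ya, :] & m[xb, yb, :]
        i = lv[xa, ya, :][both]
        j = lv[xb, yb, :][both]
        np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise NoPairsError(
            f"no in-mask voxel pair for {direction} offset {offset_voxels}")
    return CooccurrenceMatrix(counts / total, direction, offset_voxels)


def glcm_energy(m: CooccurrenceMatrix) -> float:
    """Angular second moment, sum of squared pair probabilities; in (0, 1]."""
    return float(np.sum(m.g ** 2))


def glcm_entropy(m: CooccurrenceMatrix) -> float:
    """Co-occurrence entropy in bits, ``-sum g log2 g`` over nonzero cells."""
    g = m.g[m.g > 0]
    return float(-np.sum(g * np.log2(g)))


def glcm_feature_set(m: CooccurrenceMatrix) -> dict[str, float]:
    """The seven GLCM base features (indices ``i, j`` run from 1)."""
    g = m.g
    L = m.L
    idx = np.arange(1, L + 1, dtype=np.float64)
    I = idx[:, None]
    J = idx[None, :]
    diff = I - J
    px = g.sum(axis=1)
    mu_x = float(np.sum(idx * px))
    var_x = float(np.sum((idx - mu_x) ** 2 * px))
    # symmetric matrix: marginals coincide
    if var_x > 0:
        corr = float((np.sum(g * I * J) - mu_x * mu_x) / var_x)
    else:
        corr = 1.0
        log.warning("GLCM correlation degenerate (zero marginal variance); "
                    "using 1 by convention")
    csum = I + J - 2.0 * mu_x
    return {
        "GLCMEnergy": glcm_energy(m),
        "GLCMEntropy": glcm_entropy(m),
        "GLCMContrast": float(np.sum(g * diff ** 2)),
        "GLCMCorrelation": corr,
        "GLCMInverseDifferenceMoment": float(np.sum(g / (1.0 + diff ** 2))),
        "GLCMClusterShade": float(np.sum(g * csum ** 3)),
        "GLCMClusterProminence": float(np.sum(g * csum ** 4)),
    }


def haralick_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Haralick statistics on a (direction-averaged) co-occurrence matrix."""
    g = m.g
    L = m.L
    idx = np.arange(1, L + 1, dtype=np.float64)
    I = idx[:, None]
    J = idx[None, :]

    def _ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    # p_{x+y}: sums 2..2L ; p_{x-y}: |i-j| 0..L-1
    ksum = (I + J).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=g.ravel(), minlength=2 * L + 1)
    kdiff = np.abs(I - J).astype(int)
    p_diff = np.bincount(kdiff.ravel(), weights=g.ravel(), minlength=L)

    px = g.sum(axis=1)
    py = g.sum(axis=0)
    hx, hy, hxy = _ent(px), _ent(py), _ent(g.ravel())
    pxpy = px[:, None] * py[None, :]
    nz = (g > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(g[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return {
        "HaralickSumAverage": float(np.sum(np.arange(p_sum.size) * p_sum)),
        "HaralickSumEntropy": _ent(p_sum),
        "HaralickDifferenceEntropy": _ent(p_diff),
        "HaralickIMC1": imc1,
        "HaralickIMC2": imc2,
        "HaralickAutocorrelation": float(np.sum(g * I * J)),
        "HaralickDissimilarity": float(np.sum(g * np.abs(I - J))),
    }


# ---------------------------------------------------------------------------
# run-length matrix

def rlm(grey: GreyVolume, direction: str, step: int) -> RunLengthTable:
    """Grey-level run-length table at one direction and scan stride.

    For every axial slice, lines along the direction are sampled every
    ``step`` voxels (lattice anchored at slice index 0, so a step of 1 scans
    every voxel); maximal runs of equal grey level whose lattice points all
    lie inside the mask are counted into ``counts[level, length - 1]``.  A
    masked-out lattice point (or a gap in the mask along the line)
    terminates the run.  Raises if the mask intersects no lattice point.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    m = grey.mask.values
    if not m.any():
        raise ValueError("empty mask")
    x, y, z = np.nonzero(m)
    g = grey.levels[x, y, z].astype(np.int64)
    di, dj = DIRECTIONS[direction]
    s = step
    if (di, dj) == (0, 1):
        line_a, phase, pos = x, y % s, y // s
    elif (di, dj) == (1, 0):
        line_a, phase, pos = y, x % s, x // s
    elif (di, dj) == (1, 1):
        line_a, phase, pos = x - y, x % s, x // s
    else:  # (1, -1)
        line_a, phase, pos = x + y, x % s, x // s
    # lattice anchored at slice index 0: keep phase-0 samples only
    keep = phase == 0
    if not keep.any():
        raise ValueError(
            f"mask intersects no scan-lattice point for {direction} step {s}")
    g, pos, z, line_a = g[keep], pos[keep], z[keep], line_a[keep]
    order = np.lexsort((pos, line_a, z))
    g, pos = g[order], pos[order]
    za, la = z[order], line_a[order]
    brk = np.ones(g.size, dtype=bool)
    if g.size > 1:
        same_line = (za[1:] == za[:-1]) & (la[1:] == la[:-1])
        contiguous = pos[1:] - pos[:-1] == 1
        same_grey = g[1:] == g[:-1]
        brk[1:] = ~(same_line & contiguous & same_grey)
    run_id = np.cumsum(brk) - 1
    lengths = np.bincount(run_id)
    run_grey = g[brk]
    max_level = int(run_grey.max())
    max_len = int(lengths.max())
    counts = np.zeros((max_level + 1, max_len), dtype=np.float64)
    np.add.at(counts, (run_grey, lengths - 1), 1.0)
    return RunLengthTable(counts, n_r=int(lengths.size),
                          direction=direction, step=step)


def rlm_feature_set(t: RunLengthTable) -> dict[str, float]:
    """The eleven run-emphasis base features.

    The grey index ``i`` is the stored level value (rows of the table) and
    must start at 1; the run length ``j`` is the column index plus one.
    """
    p = t.counts
    if p[0].sum() > 0:
        raise ValueError("run-length table contains grey level 0; "
                         "feed 1-based levels")
    n_r = float(t.n_r)
    I = np.arange(p.shape[0], dtype=np.float64)[:, None]
    J = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_i2 = np.where(I > 0, 1.0 / np.where(I > 0, I, 1) ** 2, 0.0)
    inv_j2 = 1.0 / J ** 2
    n_voxels = float(np.sum(p * J))  # voxels on the scan lattice
    return {
        "ShortRunEmphasis": float(np.sum(p * inv_j2) / n_r),
        "LongRunEmphasis": float(np.sum(p * J ** 2) / n_r),
        "GreyLevelNonuniformity": float(np.sum(p.sum(axis=1) ** 2) / n_r),
        "RunLengthNonuniformity": float(np.sum(p.sum(axis=0) ** 2) / n_r),
        "RunPercentage": float(n_r / n_voxels),
        "LowGreyLevelRunEmphasis": float(np.sum(p * inv_i2) / n_r),
        "HighGreyLevelRunEmphasis": float(np.sum(p * I ** 2) / n_r),
        "ShortRunLowGreyLevelEmphasis": float(np.sum(p * inv_i2 * inv_j2) / n_r),
        "ShortRunHighGreyLevelEmphasis": float(np.sum(p * I ** 2 * inv_j2) / n_r),
        "LongRunLowGreyLevelEmphasis": float(np.sum(p * inv_i2 * J ** 2) / n_r),
        "LongRunHighGreyLevelEmphasis": float(np.sum(p * I ** 2 * J ** 2) / n_r),
    }


# ---------------------------------------------------------------------------
# first-order and shape families

def histogram_features(volume: VoxelGrid, mask: ROIMask,
                       entropy_bins: int = 32) -> dict[str, float]:
    """42 first-order statistics of the masked intensities.

    Percentiles use linear interpolation between order statistics; histogram
    entropy and uniformity use ``entropy_bins`` equal-width bins over the
    masked range; the mode is the centre of the modal bin of that histogram.
    Dispersion statistics of a constant (or single-voxel) region are 0.
    """
    mask.check_aligned(volume)
    v = np.asarray(volume.values, dtype=np.float64)[mask.values]
    if v.size == 0:
        raise ValueError("empty mask")
    if v.size == 1:
        log.warning("histogram features on a single-voxel mask; "
                    "dispersion statistics are 0")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    med = float(np.median(v))
    lo, hi = float(v.min()), float(v.max())
    q1, q3 = (float(np.percentile(v, q)) for q in (25, 75))
    p1, p99 = (float(np.percentile(v, q)) for q in (1, 99))
    if hi > lo:
        hist, edges = np.histogram(v, bins=entropy_bins, range=(lo, hi))
        p = hist / hist.sum()
        pnz = p[p > 0]
        entropy = float(-np.sum(pnz * np.log2(pnz)))
        uniformity = float(np.sum(p ** 2))
        mode = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
        n = v.size
        m2 = sd ** 2
        m3 = float(np.mean((v - mean) ** 3))
        m4 = float(np.mean((v - mean) ** 4))
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0  # excess kurtosis
    else:
        entropy, uniformity, mode = 0.0, 1.0, mean
        skew = kurt = 0.0
    top = v[v >= np.percentile(v, 90)]
    out = {
        "MinIntensity": lo,
        "MaxIntensity": hi,
        "RangeIntensity": hi - lo,
        "MeanIntensity": mean,
        "MedianIntensity": med,
        "ModeIntensity": mode,
        "StandardDeviation": sd,
        "Variance": sd ** 2,
        "MeanAbsoluteDeviation": float(np.mean(np.abs(v - mean))),
        "MedianAbsoluteDeviation": float(np.median(np.abs(v - med))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(v ** 2)),
        "RootMeanSquare": float(np.sqrt(np.mean(v ** 2))),
        "HistogramEntropy": entropy,
        "Uniformity": uniformity,
        "CoefficientOfVariation": sd / mean if mean != 0 else 0.0,
        "InterquartileRange": q3 - q1,
        "QuartileDispersion": (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else 0.0,
        "Percentile01": p1,
        "Percentile99": p99,
        "Percentile99Minus01": p99 - p1,
        "MeanTopDecile": float(top.mean()),
    }
    for q in range(5, 100, 5):
        out[f"Percentile{q:02d}"] = float(np.percentile(v, q))
    return out


def _max_diameter(coords: np.ndarray) -> float:
    """Maximum pairwise distance between points; hull-reduced when large."""
    if coords.shape[0] > 400:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    if coords.shape[0] == 1:
        return 0.0
    return float(distance.pdist(coords).max())


def shape_features(mask: ROIMask) -> dict[str, float]:
    """Nine shape factors of the binary mask, in mm units.

    Volume is voxel count times voxel volume; surface area counts exposed
    voxel faces.  Sphericity is ``pi^(1/3) (6V)^(2/3) / A``; elongation is
    the square root of the ratio of the second to the first principal second
    moment of the voxel centres.  A disconnected mask is measured on the
    union of its components with a warning.
    """
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(m, structure=np.ones((3, 3, 3)))[1]
    if n_comp > 1:
        log.warning("shape features on a disconnected mask (%d components); "
                    "computed on their union", n_comp)
    sx, sy, sz = mask.spacing_mm
    vol = m.sum() * mask.voxel_volume_mm3
    padded = np.pad(m, 1)
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        area += np.count_nonzero(np.diff(padded, axis=axis)) * fa
    sphericity = np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / area
    # boundary voxels suffice for the diameter
    interior = ndimage.binary_erosion(m)
    boundary = m & ~interior
    coords = np.argwhere(boundary if boundary.any() else m) * np.array(
        [sx, sy, sz])
    centred = np.argwhere(m) * np.array([sx, sy, sz])
    centred = centred - centred.mean(axis=0)
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    return {
        "Volume": float(vol),
        "SurfaceArea": float(area),
        "SurfaceToVolumeRatio": float(area / vol),
        "Sphericity": float(sphericity),
        "Compactness1": float(vol / (np.sqrt(np.pi) * area ** 1.5)),
        "Compactness2": float(36.0 * np.pi * vol ** 2 / area ** 3),
        "SphericalDisproportion": float(1.0 / sphericity),
        "Maximum3DDiameter": _max_diameter(coords),
        "Elongation": elongation,
    }


# ---------------------------------------------------------------------------
# direction variants and the full catalog

def direction_variants(per_direction: dict[str, float]) -> dict[str, float]:
    """Expand per-angle values into the six named variants.

    Degenerate directions (NaN values) are excluded from the mean and the
    population SD, with a log note.
    """
    vals = np.array([per_direction.get(d, np.nan) for d in _DIR_NAMES])
    finite = vals[np.isfinite(vals)]
    if finite.size < vals.size:
        log.warning("direction variants: %d degenerate direction(s) excluded",
                    vals.size - finite.size)
    out = {d: float(v) for d, v in zip(_DIR_NAMES, vals)}
    if finite.size:
        out["AllDirection"] = float(finite.mean())
        out["AllDirection_SD"] = float(finite.std(ddof=0))
    else:
        out["AllDirection"] = np.nan
        out["AllDirection_SD"] = np.nan
    return out


def _variant_names(base: str, offset: int) -> list[str]:
    return ([f"{base}_{d}_offset{offset}" for d in _DIR_NAMES]
            + [f"{base}_AllDirection_offset{offset}",
               f"{base}_AllDirection_offset{offset}_SD"])


def build_catalog(offsets: tuple[int, ...] = OFFSETS) -> list[str]:
    """The ordered 396-name feature catalog (per modality)."""
    names = list(HISTOGRAM_NAMES) + list(SHAPE_NAMES)
    names += [f"{b}_offset{o}" for b in HARALICK_BASES for o in offsets]
    for base in GLCM_BASES:
        for o in offsets:
            names += _variant_names(base, o)
    for base in RLM_BASES:
        for o in offsets:
            names += _variant_names(base, o)
    if len(names) != len(set(names)):
        raise RuntimeError("catalog names are not unique")
    return names


def extract_all(volume: VoxelGrid, mask: ROIMask, levels: int = 32,
                offsets: tuple[int, ...] = OFFSETS) -> pd.Series:
    """Extract the full per-modality feature vector for one subject.

    ``volume`` should be the preprocessed (isotropic, grey-normalized)
    image; matrix families are re-binned to ``levels`` grey levels over the
    masked range.  Families that fail for a direction record NaN for that
    direction rather than dropping the feature.
    """
    mask.check_aligned(volume)
    values: dict[str, float] = {}
    values.update(histogram_features(volume, mask))
    values.update(shape_features(mask))

    grey = discretize(volume, mask, levels)
    grey_rlm = GreyVolume(grey.levels + 1, L=levels + 1, mask=mask,
                          spacing_mm=grey.spacing_mm)

    for o in offsets:
        mats: dict[str, CooccurrenceMatrix | None] = {}
        for d in _DIR_NAMES:
            try:
                mats[d] = glcm(grey, d, o)
            except NoPairsError:
                log.warning("GLCM %s offset %d: no pairs; recorded missing", d, o)
                mats[d] = None
        per_dir = {d: (glcm_feature_set(m) if m is not None else None)
                   for d, m in mats.items()}
        for base in GLCM_BASES:
            dirvals = {d: (fs[base] if fs is not None else np.nan)
                       for d, fs in per_dir.items()}
            for suffix, val in direction_variants(dirvals).items():
                if suffix in ("AllDirection", "AllDirection_SD"):
                    tail = (f"{base}_AllDirection_offset{o}"
                            + ("_SD" if suffix.endswith("SD") else ""))
                else:
                    tail = f"{base}_{suffix}_offset{o}"
                values[tail] = val
        avail = [m.g for m in mats.values() if m is not None]
        if avail:
            avg = CooccurrenceMatrix(np.mean(avail, axis=0), "AllDirection", o)
            values.update({f"{k}_offset{o}": v
                           for k, v in haralick_features(avg).items()})
        else:
            values.update({f"{b}_offset{o}": np.nan for b in HARALICK_BASES})

    for o in offsets:
        per_dir_rlm = {}
        for d in _DIR_NAMES:
            try:
                per_dir_rlm[d] = rlm_feature_set(rlm(grey_rlm, d, o))
            except ValueError:
                log.warning("RLM %s step %d failed; recorded missing", d, o)
                per_dir_rlm[d] = None
        for base in RLM_BASES:
            dirvals = {d: (fs[base] if fs is not None else np.nan)
                       for d, fs in per_dir_rlm.items()}
            for suffix, val in direction_variants(dirvals).items():
                if suffix in ("AllDirection", "AllDirection_SD"):
                    tail = (f"{base}_AllDirection_offset{o}"
                            + ("_SD" if suffix.endswith("SD") else ""))
                else:
                    tail = f"{base}_{suffix}_offset{o}"
                values[tail] = val

    catalog = build_catalog(offsets)
    missing = set(catalog) - set(values)
    if missing:
        raise RuntimeError(f"catalog names not computed: {sorted(missing)[:5]}")
    return pd.Series([values[n] for n in catalog], index=catalog, dtype=float)
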