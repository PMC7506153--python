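"""Synthetic paired PET/MR phantom cohort with two stage classes.

Each subject carries an ellipsoidal lesion on a quiet background.  The lesion
signal is a smooth radial profile modulated by a correlated Gaussian texture
field, ``profile * (1 + field)``, clipped nonnegative and rescaled so the
subject's drawn peak SUV is attained exactly at the hottest voxel.  The two
stage classes (0 = early, 1 = advanced) differ by configurable effect sizes
in lesion radius, peak uptake, texture correlation length and texture
amplitude; advanced lesions are by default larger, hotter and more
heterogeneous.  The MR volume shares the lesion mask but carries an
independent texture field on an arbitrary 0-1000 intensity scale.

A per-subject heterogeneity amplitude optionally scales with lesion volume
(``heterogeneity_volume_coupling``), planting the positive texture-vs-TLG
correlations that the association stage is expected to recover.

Everything is a deterministic function of ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import ROIMask, VoxelGrid

__all__ = ["PhantomSpec", "SubjectRecord", "generate_cohort", "iter_cohort",
           "sample_covariates", "cohort_table"]

_CLASSES = ("early", "advanced")


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition parameters of the phantom cohort.

    Per-class parameters are ``{"early": ..., "advanced": ...}`` mappings;
    radius and peak entries are ``(mean, sd)`` pairs.
    """

    n_subjects: int = 100
    train_fraction: float = 0.7
    class_prevalence: float = 0.73          # fraction of advanced cases
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_mm: dict = field(default_factory=lambda: {
        "early": (9.0, 1.5), "advanced": (13.0, 2.0)})
    lesion_suv_peak: dict = field(default_factory=lambda: {
        "early": (8.0, 2.5), "advanced": (11.5, 3.5)})
    heterogeneity_corr_len_mm: dict = field(default_factory=lambda: {
        "early": 6.0, "advanced": 3.0})
    heterogeneity_sd: dict = field(default_factory=lambda: {
        "early": 0.10, "advanced": 0.30})
    heterogeneity_volume_coupling: float = 0.5
    background_suv: float = 1.5
    noise_sd: float = 0.2
    mr_background: float = 300.0
    mr_lesion_mean: float = 600.0
    mr_noise_sd: float = 15.0
    lesion_plateau: float = 0.7             # flat-core fraction of the radius
    radius_jitter: float = 0.2              # per-axis radius jitter (+-20 %)
    center_jitter_mm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(f"need at least 4 subjects, got {self.n_subjects}")
        if not (0 < self.train_fraction < 1):
            raise ValueError(f"train fraction must be in (0, 1), "
                             f"got {self.train_fraction}")
        if not (0 < self.class_prevalence < 1):
            raise ValueError("class prevalence must be in (0, 1)")
        if self.noise_sd < 0 or self.mr_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")
        for cls in _CLASSES:
            r_mean, r_sd = self.lesion_radius_mm[cls]
            if r_sd < 0 or self.lesion_suv_peak[cls][1] < 0:
                raise ValueError("per-class sds must be nonnegative")
            if self.heterogeneity_sd[cls] < 0:
                raise ValueError("heterogeneity sd must be nonnegative")
            # worst-case lesion must fit inside the grid with jitter margin
            r_max = (r_mean + 3.0 * r_sd) * (1.0 + self.radius_jitter)
            half_extent = min(n * s / 2.0 for n, s in
                              zip(self.grid_shape, self.voxel_spacing_mm))
            if r_max + self.center_jitter_mm >= half_extent:
                raise ValueError(
                    f"{cls} lesion (radius up to {r_max:.1f} mm) does not fit "
                    f"inside the grid (half-extent {half_extent:.1f} mm)")


@dataclass
class SubjectRecord:
    subject_id: str
    stage_label: int              # 0 = early (I/II), 1 = advanced (III/IV)
    age: float
    gender: str                   # "M" / "F"
    pet_volume: VoxelGrid
    mr_volume: VoxelGrid
    lesion_mask: ROIMask


def sample_covariates(spec: PhantomSpec, rng: np.random.Generator
                      ) -> tuple[float, str]:
    """Age ~ N(52, 12.5) truncated to [18, 90]; gender ~ Bernoulli(0.78 male).

    Cosmetic covariates: they carry no class signal.
    """
    a, b = (18.0 - 52.0) / 12.5, (90.0 - 52.0) / 12.5
    age = float(stats.truncnorm.rvs(a, b, loc=52.0, scale=12.5,
                                    random_state=rng))
    gender = "M" if rng.random() < 0.78 else "F"
    return age, gender


def _correlated_field(shape, spacing, corr_len_mm: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with a given correlation length.

    White noise is smoothed with a Gaussian kernel whose width (in voxels)
    equals the correlation length, then renormalized to unit variance.
    """
    white = rng.standard_normal(shape)
    sigma = [max(corr_len_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_subject(spec: PhantomSpec, subject_id: str, label: int,
                  rng: np.random.Generator) -> SubjectRecord:
    cls = _CLASSES[label]
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.voxel_spacing_mm)

    r_mean, r_sd = spec.lesion_radius_mm[cls]
    base_r = max(2.0, rng.normal(r_mean, r_sd))
    jit = rng.uniform(1.0 - spec.radius_jitter, 1.0 + spec.radius_jitter, size=3)
    radii = base_r * jit
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    center = extent / 2.0 + rng.uniform(-spec.center_jitter_mm,
                                        spec.center_jitter_mm, size=3)

    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    rho2 = sum(((c - mu) / r) ** 2
               for c, mu, r in zip((xs, ys, zs), center, radii))
    mask_arr = rho2 <= 1.0
    if not mask_arr.any():
        raise ValueError(f"{subject_id}: lesion produced an empty mask")
    edge_touch = (mask_arr[0].any() or mask_arr[-1].any()
                  or mask_arr[:, 0].any() or mask_arr[:, -1].any()
                  or mask_arr[:, :, 0].any() or mask_arr[:, :, -1].any())
    if edge_touch:
        raise ValueError(f"{subject_id}: lesion touches the grid boundary")

    # Smooth ellipsoid profile: flat core with a cosine rim taper, so
    # within-lesion contrast is dominated by the planted texture field
    # rather than by the radial gradient.
    rho = np.sqrt(rho2)
    t = np.clip((rho - spec.lesion_plateau) / (1.0 - spec.lesion_plateau),
                0.0, 1.0)
    profile = np.where(rho <= 1.0, 0.5 * (1.0 + np.cos(np.pi * t)), 0.0)

    # per-subject texture amplitude, optionally coupled to lesion volume
    het_sd = spec.heterogeneity_sd[cls]
    if spec.heterogeneity_volume_coupling and het_sd > 0:
        vol_ratio = (np.prod(radii) / r_mean ** 3) ** (
            spec.heterogeneity_volume_coupling)
        het_sd = het_sd * float(vol_ratio)
    corr_len = spec.heterogeneity_corr_len_mm[cls]

    peak = max(2.0, rng.normal(*spec.lesion_suv_peak[cls]))
    field_pet = _correlated_field(shape, spacing, corr_len, rng)
    lesion = np.clip(profile * (1.0 + het_sd * field_pet), 0.0, None)
    lmax = lesion.max()
    if lmax > 0:
        lesion *= peak / lmax
    pet = np.maximum(spec.background_suv, lesion)
    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, size=shape)
    pet = np.clip(pet, 0.0, None).astype(np.float32)

    field_mr = _correlated_field(shape, spacing, corr_len, rng)
    mr_contrast = spec.mr_lesion_mean - spec.mr_background
    mr = spec.mr_background + profile * (1.0 + het_sd * field_mr) * mr_contrast
    if spec.mr_noise_sd > 0:
        mr = mr + rng.normal(0.0, spec.mr_noise_sd, size=shape)
    mr = np.clip(mr, 0.0, 1000.0).astype(np.float32)

    age, gender = sample_covariates(spec, rng)
    return SubjectRecord(
        subject_id=subject_id,
        stage_label=label,
        age=age,
        gender=gender,
        pet_volume=VoxelGrid(pet, spacing_mm=spacing),
        mr_volume=VoxelGrid(mr, spacing_mm=spacing),
        lesion_mask=ROIMask(mask_arr, spacing_mm=spacing),
    )


def iter_cohort(spec: PhantomSpec) -> Iterator[SubjectRecord]:
    """Yield subjects one at a time (volumes can be discarded after use)."""
    spec.validate()
    master = np.random.default_rng(spec.seed)
    labels = (master.random(spec.n_subjects) < spec.class_prevalence
              ).astype(int)
    # guarantee both classes are present
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    width = max(3, len(str(spec.n_subjects)))
    for k in range(spec.n_subjects):
        rng = np.random.default_rng(children[k])
        yield _make_subject(spec, f"S{k + 1:0{width}d}", int(labels[k]), rng)


def generate_cohort(spec: PhantomSpec) -> list[SubjectRecord]:
    """Materialize the whole cohort (use :func:`iter_cohort` for large runs)."""
    return list(iter_cohort(spec))


def cohort_table(records: list[SubjectRecord],
                 split: pd.Series | None = None) -> pd.DataFrame:
    """Cohort metadata table (subject_id, stage_label, age, gender[, split])."""
    df = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "stage_label": [r.stage_label for r in records],
        "age": [round(r.age, 2) for r in records],
        "gender": [r.gender for r in records],
    }).set_index("subject_id")
    if split is not None:
        df["split"] = split.reindex(df.index)
    return df
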