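# Methods

This note records the models, conventions and design choices behind
`radstage`, at the level of detail a maintainer needs to modify the
pipeline without re-deriving its decisions.

## Phantom cohort model

Each subject is a 64×64×64 voxel field of view at 1 mm isotropic spacing
carrying one ellipsoidal lesion. The lesion signal is

```
lesion(x) = profile(ρ(x)) · (1 + σ_het · F(x)),   clipped at 0,
```

where ρ is the normalized ellipsoidal radius, `F` is a unit-variance
Gaussian random field (white noise smoothed with a Gaussian kernel whose
width equals the class's correlation length, then renormalized) and
σ_het the planted texture amplitude. The profile has a **flat core with a
cosine rim taper** (plateau at 70 % of the radius): with a pure `1 − ρ²`
profile, within-lesion contrast is dominated by the radial gradient, and
— because larger lesions have shallower gradients — co-occurrence entropy
*decreases* with lesion size, inverting the texture–metabolism coupling
the cohort is required to plant. With a flat core the texture field
dominates in-lesion contrast and entropy rises with both amplitude and
lesion volume. After texturing, the lesion is rescaled so its hottest
voxel equals the subject's drawn peak SUV, which keeps the cohort SUVmax
distribution at the intended scale independent of the texture settings.
PET background is constant (SUV 1.5) combined by `max`, plus Gaussian
noise (σ = 0.2 SUV) clipped at zero. The MR volume shares the mask but
has an independent texture field on an arbitrary 0–1000 scale
(background 300, lesion plateau 600, σ = 15).

Default class parameters (chosen once; the source analysis publishes no
per-class lesion-size or texture statistics, only cohort-level metabolic
summaries):

| parameter | early | advanced | rationale |
|---|---|---|---|
| prevalence | 0.27 | 0.73 | published stage distribution 27/73 |
| lesion radius (mm) | 9 ± 1.5 | 13 ± 2 | primary NPC scale; fits a 64 mm grid with jitter |
| peak SUV | 8.0 ± 2.5 | 11.5 ± 3.5 | mixture mean ≈ 10.5, matching the published cohort SUVmax 10.91 ± 4.76 |
| texture correlation length (mm) | 6 | 3 | advanced lesions rougher at fixed amplitude |
| texture amplitude σ_het | 0.10 | 0.30 | separates classes without saturating entropy |

Per-axis radii are jittered ±20 % (ellipsoids, not spheres, so shape
features are non-trivial), the centre by ±2 mm. The per-subject amplitude
is scaled by `(V/V̄_class)^κ` with coupling κ = 0.5, planting the positive
texture-vs-TLG correlation the association stage recovers. Age
(N(52, 12.5²) truncated to [18, 90]) and gender (78 % male) are cosmetic
covariates with no class signal. Everything derives from one seed via
`numpy.random.SeedSequence` spawning, so a spec reproduces its cohort bit
for bit.

**What the phantom does not emulate:** acquisition physics (attenuation,
partial volume, reconstruction artifacts), anatomical background
structure, nodal/metastatic disease, registration error between PET and
MR, and any real relationship between texture and biology. Passing tests
therefore demonstrate that the pipeline recovers *planted* effects of the
stated sizes from images with realistic dimensions and value ranges — not
that the staging models would perform comparably on patients.

## Preprocessing conventions

Voxel centres sit at `origin + (k + 0.5)·spacing`; resampled shapes are
`ceil(extent/target)`, so resampling a volume already at target spacing is
exactly the identity on voxel centres. Images use trilinear interpolation,
masks nearest-neighbour (the alphabet {0,1} must survive). Grey
normalization maps the volume minimum/maximum to 0/255 with rounding half
away from zero; it is computed over the whole volume, not the ROI, so
within-lesion minima (`MinIntensity`) stay informative. A constant volume
normalizes to all zeros with a warning. Metabolic parameters are computed
on the resampled but *un-normalized* SUV volume; texture features on the
normalized volumes.

## Texture catalog

The catalog is fixed at 396 names per modality: 42 histogram + 9 shape +
21 Haralick (7 × 3 offsets) + 126 GLCM (7 bases × 3 offsets × 6 variants)
+ 198 RLM (11 bases × 3 steps × 6 variants). The six variants per base and
offset are the four in-plane angles, their mean and their population SD.
Directions are 2D in-plane within axial slices, accumulated over slices
(the angle0/45/90/135 naming is a 2D convention). Matrix features re-bin
the masked intensities into 32 equal-width levels — a balance between
level resolution and matrix sparsity at lesion sizes of 10³–10⁴ voxels.

Conventions that matter for reproducing values:

- GLCMs are symmetrized (both orderings counted) and normalized per
  direction/offset; moment features (correlation, cluster shade/
  prominence, autocorrelation, sum average) use matrix indices 1..L.
  Degenerate correlation (zero marginal variance) is 1 by convention.
- The RLM "step" is a scan-lattice stride: runs are counted on every
  step-th voxel along the direction, lattice anchored at slice index 0, so
  step 1 is the classical GLRLM. Run-emphasis features use the stored grey
  value as the index i and reject level 0; the extraction pipeline feeds
  the RLM branch 1-based levels (discretized + 1), which keeps `1/i²`
  emphases finite and makes hand-enumerated tables read literally.
- Run percentage is runs divided by scanned in-mask lattice voxels
  (= Σ j·p), keeping it in (0, 1] for every stride.
- Haralick features are computed on the direction-averaged GLCM per
  offset, and the family is disjoint from the GLCM family by construction.
- Histogram entropy/uniformity/mode use 32 equal-width bins over the
  masked range; percentiles interpolate linearly between order statistics;
  dispersion statistics of a constant or single-voxel region are 0.
- Shape: surface area counts exposed voxel faces (note this inflates
  curved surfaces by a staircase factor of up to ~1.5 — digital-sphere
  sphericities are comparable between face-counted shapes, not with the
  analytic sphere); maximum 3D diameter reduces to convex-hull vertices
  above 400 boundary voxels; elongation is √(λ₂/λ₁) of the voxel-centre
  second moments. A disconnected mask is measured on the union with a
  warning.
- A direction with no valid pair/run records NaN and is excluded from the
  mean/SD variants with a log note; failures are recorded, never silently
  dropped.

## Metabolic parameters

The seed box is the anatomical mask's bounding box dilated by 3 voxels — a
deterministic stand-in for the operator's box adjustment. Within the box,
voxels at ≥ 40 % of the box SUVmax are kept and restricted to the
26-connected component containing the maximum voxel, automating the manual
exclusion of nearby physiologic uptake. MTV is measured on this metabolic
mask (the 40 % boundary defines the tumor for metabolic purposes), while
texture features use the anatomical mask — the two segmentation routes are
intentionally distinct. SUV conversion assumes unit tissue density, under
which SUV = concentration(kBq/mL) × weight(kg) / dose(MBq).

## Selection and staging

Cleaning: per feature, training values with |z| > 3 (and NaNs) are
replaced by the mean of the remaining training values, then standardized
with post-replacement training statistics; test rows are transformed with
training parameters only, and zero-variance features are dropped with a
warning. The z = 3 cutoff is this package's choice.

mRMR uses the MID (difference) criterion with plug-in mutual information
after 10-quantile equal-frequency discretization of each feature; ties
break in catalog order. The L1-logistic path spans 50 log-spaced penalties
from just above λ_max = max|Xᵀ(y − ȳ)|/n (where every coefficient is
exactly zero) down three decades; the CV criterion is mean 10-fold
stratified misclassification error at probability 0.5, minimum rule (not
1-SE), with ties preferring the sparser (larger) penalty. PET and MR
tables are processed independently; no fused model is fitted.

The staging fit is unpenalized maximum likelihood; detected separation
(non-convergence or runaway coefficients) falls back to a vanishing ridge
(10⁻⁶) with a warning. The radscore is the linear predictor. The headline
test metrics use the *training* Youden cutoff (lower cutoff on ties);
each cohort's own optimal cutoff is reported alongside, mirroring the
per-cohort reporting style of the source analysis. Calibration uses 10
equal-width probability bins and a least-squares line through the
nonempty bin points.

The recovery property for selection (5 planted features of effect d = 1
among 396; ≥ 4 in mRMR's top 20 in ≥ 90 % of 50 replicates) is evaluated
on tables of n = 140 — the same simulation scale as the L1-selection
checks. At the pipeline's own training size (n = 70) a d = 1 signal sits
at the edge of what a 10-bin plug-in MI estimate can separate from the
upper tail of 391 noise features, and recovery drops to ~25 %; this is an
estimator noise floor, not an implementation artifact (coarser 3–4 bin
estimators reach only ~80–85 % at n = 70).

## Association statistics

Pearson r with two-sided p from t = r√((n−2)/(1−r²)); zero-variance
vectors report NaN. Cohort comparisons use the pooled-variance two-sample
t (reported as group 2 − group 1, matching the published table's
testing-minus-training orientation) and Pearson χ² without continuity
correction. Correlations are computed over the full cohort (train + test)
to maximize n; significance flags are * (p < 0.05) and ** (p < 0.01) with
no multiple-testing correction. Recomputing the published SUVmax row from
its rounded summaries gives t = −0.898 against the printed −0.899; the
original was evidently computed from unrounded data, so that comparison
carries a ±0.002 tolerance.

## Pipeline and reproducibility

The orchestrator streams subjects (generate → preprocess → extract →
measure) so the 100-subject default fits in memory, then splits, selects,
fits and correlates per modality, failing fast with the offending stage
named. Stage seeds derive from the single config seed by hashing the stage
name (CRC32, kept below 2³¹), so no two stages share a stream and a config
reproduces the run bit for bit; the manifest records SHA-256 checksums of
every tabular artifact and the config. All tabular interchange is CSV
(fixed float format) for inspectability; volumes are NIfTI with spacing in
the affine.

Problem sizes used by the test and acceptance suites: the full default
cohort (n = 100, 64³ voxels, ~25 s end to end) for the staging and
correlation checks; a 16-subject configuration for orchestration and
determinism checks; 40³ grids for generator property tests; 8×8×3 grey
volumes for brute-force texture equivalence; and 50-replicate
metadata-level simulations for the selection-recovery and type-I-error
properties.

## Known limitations

- The feature catalog is this package's own fixed definition of the five
  families with the published total (396) and the published selected-
  feature names; commercial implementations will not match it
  name-for-name or value-for-value.
- 2D in-plane texture only by default; no filtered-image (wavelet/LoG)
  features, no GLSZM/NGTDM families, no IBSI certification.
- Youden-cutoff choice and per-cohort cutoff reporting reconstruct an
  unpublished procedure; the radscore is defined as the logistic linear
  predictor.
- The phantom's nearly separable classes make the staging AUCs optimistic
  by design; they validate recovery machinery, not clinical performance.
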