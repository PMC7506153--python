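# radstage

A tested, reusable re-implementation of a PET/MR radiomics staging analysis
for nasopharyngeal carcinoma (NPC), driven by a synthetic phantom-cohort
generator so that every stage is exercisable without patient data.

NPC staging (early, TNM I–II, vs. advanced, III–IV) guides the choice
between radiotherapy alone and chemoradiation. The analysis asks two
questions: can quantitative texture features extracted from co-registered
¹⁸F-FDG-PET and T2-weighted MR volumes stage the primary lesion, and how do
those features relate to the lesion's metabolic burden?

## What the pipeline computes

1. **Preprocessing** — volumes are resampled to 1 mm isotropic (trilinear;
   nearest-neighbour for masks) and grey levels linearly normalized to
   0–255.
2. **Radiomics catalog** — 396 named features per modality over the
   anatomical lesion mask: 42 histogram statistics, 9 shape factors,
   21 Haralick features, 126 grey-level co-occurrence (GLCM) features and
   198 run-length (RLM) features. Matrix families use in-plane directions
   0°/45°/90°/135° at offsets/steps 1, 4 and 7, each with per-angle values
   plus their mean (`AllDirection`) and standard deviation (`_SD`).
   Representative definitions, with g(i,j) the symmetrized pair-probability
   matrix and p(i,j,θ) the run-length table (nᵣ runs):

   - GLCM energy `Σᵢⱼ g(i,j)²`, entropy `−Σᵢⱼ g log₂ g`
   - HGRE `(1/nᵣ) Σᵢⱼ p(i,j,θ) i²`, LGRE `(1/nᵣ) Σᵢⱼ p(i,j,θ)/i²`,
     SRHGE `(1/nᵣ) Σᵢⱼ p(i,j,θ) i²/j²`
3. **PET metabolic parameters** — SUV = concentration · weight / dose;
   the metabolic ROI is delineated at 40 % of the in-box SUVmax (connected
   component containing the maximum); MTV = mask volume in mL and
   TLG = SUVmean × MTV.
4. **Feature selection** — stratified 7:3 train/test split; training-side
   outlier replacement (|z| > 3 → inlier mean) and z-score
   standardization; greedy mRMR (mutual-information difference criterion)
   down to 20 candidates; L1-penalized logistic regression over a 50-point
   λ grid with the penalty chosen by 10-fold cross-validated
   misclassification error.
5. **Staging models** — unpenalized logistic regression per modality; the
   linear predictor is the per-subject *radscore*
   `radscore = β₀ + Σ βᵢ xᵢ`; evaluation by ROC/AUC, a Youden-index
   radscore cutoff fixed on the training cohort, and 10-bin calibration
   curves.
6. **Association analysis** — Pearson correlation of the selected features
   with SUVmax/MTV/TLG, and train-vs-test cohort comparison (pooled
   t-tests, Pearson χ²).

The phantom generator plants the class structure the models must recover:
advanced lesions are larger, hotter, and texturally more heterogeneous
(shorter correlation length, higher amplitude), and texture amplitude is
coupled to lesion volume so entropy-type features correlate positively with
metabolic burden.

## Worked example

```python
from radstage import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))
for mod in ("pet", "mr"):
    rep = result.reports[mod]["test"]
    print(mod, round(rep.auc, 3), round(rep.accuracy, 2))
```

prints

```
pet 1.0 0.93
mr 1.0 0.93
```

i.e. on the default 100-subject phantom cohort (70 training / 30 testing)
both single-modality radscore models separate early from advanced stages
nearly perfectly on the held-out subjects — the planted class effects are
deliberately strong. The accompanying metabolic table has cohort mean
SUVmax ≈ 10.9 ± 3.7, and the tracked co-occurrence entropy feature
(`GLCMEntropy_angle0_offset4`) correlates positively with MTV (r ≈ 0.34)
and TLG (r ≈ 0.46) across the cohort, reproducing the qualitative
texture-metabolism pattern the analysis is designed around.

The step-by-step version of the same analysis lives under `analysis/`
(`01_simulate_cohort.py` … `06_correlate_metabolism.py`); each script
prints what it found and writes its tables under `results/`.

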