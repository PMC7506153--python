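"""End-to-end orchestration: simulate -> preprocess -> extract -> metabolics
-> select -> model -> correlate, for both modalities, with a reproducibility
manifest.

Subjects are processed in a streaming loop (volumes are released after
feature extraction) so the default 100-subject cohort fits comfortably in
memory.  Every random stage derives its seed from the one config seed by
hashing the stage name, so a config reproduces the whole run bit for bit;
the manifest records a SHA-256 checksum of every tabular output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, metabolics, preprocessing, selection, staging, synthetic
from . import texture
from .io import write_mask, write_volume

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

MODALITIES = ("pet", "mr")


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    phantom: synthetic.PhantomSpec = field(
        default_factory=synthetic.PhantomSpec)
    target_spacing_mm: float = 1.0
    grey_levels: int = 32
    offsets: tuple[int, ...] = (1, 4, 7)
    mrmr_keep: int = 20
    cv_folds: int = 10
    n_lambda: int = 50
    threshold_fraction: float = 0.4
    calibration_bins: int = 10
    save_volumes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed rules the run: the generator's stream derives from it
        self.phantom = dataclasses.replace(
            self.phantom, seed=self.stage_seed("simulate"))

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2**31, derived from the config seed."""
        return zlib.crc32(f"{stage}:{self.seed}".encode()) % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        for key in ("grid_shape", "voxel_spacing_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        for key in ("lesion_radius_mm", "lesion_suv_peak"):
            if key in ph:
                ph[key] = {k: tuple(v) for k, v in ph[key].items()}
        if "offsets" in d:
            d["offsets"] = tuple(d["offsets"])
        return cls(phantom=synthetic.PhantomSpec(**ph), **d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    cohort: pd.DataFrame                       # metadata + split
    features: dict[str, pd.DataFrame]          # per modality, raw 396 columns
    metabolic_table: pd.DataFrame
    selections: dict[str, selection.SelectionResult]
    models: dict[str, staging.StageModel]
    reports: dict[str, dict[str, staging.DiagnosticReport]]
    correlations: dict[str, pd.DataFrame]
    cohort_comparison: pd.DataFrame
    manifest: dict


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _csv_bytes(df: pd.DataFrame) -> bytes:
    return df.to_csv(float_format="%.10g").encode()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _subject_tables(config: RunConfig, out_dir: str | None
                    ) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Streaming per-subject work: preprocess, extract, metabolics."""
    meta_rows = []
    feats: dict[str, list[pd.Series]] = {m: [] for m in MODALITIES}
    met_rows = []
    for rec in synthetic.iter_cohort(config.phantom):
        mask_iso = preprocessing.resample_mask(rec.lesion_mask,
                                               config.target_spacing_mm)
        pet_iso = preprocessing.resample_isotropic(rec.pet_volume,
                                                   config.target_spacing_mm)
        mr_iso = preprocessing.resample_isotropic(rec.mr_volume,
                                                  config.target_spacing_mm)
        pet_norm = preprocessing.normalize_grey(pet_iso)
        mr_norm = preprocessing.normalize_grey(mr_iso)
        for mod, vol in (("pet", pet_norm), ("mr", mr_norm)):
            vec = texture.extract_all(vol, mask_iso,
                                      levels=config.grey_levels,
                                      offsets=config.offsets)
            vec.name = rec.subject_id
            feats[mod].append(vec)
        box = metabolics.box_from_mask(mask_iso, dilate_voxels=3)
        roi = metabolics.delineate_metabolic_roi(
            pet_iso, box, config.threshold_fraction)
        summ = metabolics.metabolic_summary(pet_iso, roi)
        met_rows.append({"subject_id": rec.subject_id,
                         "suv_max": summ.suv_max, "suv_mean": summ.suv_mean,
                         "mtv_ml": summ.mtv_ml, "tlg": summ.tlg})
        meta_rows.append({"subject_id": rec.subject_id,
                          "stage_label": rec.stage_label,
                          "age": round(rec.age, 2), "gender": rec.gender})
        if out_dir and config.save_volumes:
            sdir = os.path.join(out_dir, "volumes", rec.subject_id)
            os.makedirs(sdir, exist_ok=True)
            write_volume(os.path.join(sdir, "pet.nii.gz"), rec.pet_volume)
            write_volume(os.path.join(sdir, "mr.nii.gz"), rec.mr_volume)
            write_mask(os.path.join(sdir, "mask.nii.gz"), rec.lesion_mask)
    meta = pd.DataFrame(meta_rows).set_index("subject_id")
    met = pd.DataFrame(met_rows).set_index("subject_id")
    feat_tables = {m: pd.DataFrame(feats[m]).rename_axis("subject_id")
                   for m in MODALITIES}
    return meta, feat_tables, met


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike | None = None
                 ) -> PipelineResult:
    """Run the full analysis and return all stage outputs plus the manifest."""
    out = os.fspath(out_dir) if out_dir is not None else None
    if out:
        os.makedirs(out, exist_ok=True)

    try:
        meta, feat_tables, met = _subject_tables(config, out)
    except Exception as exc:
        raise StageError(f"stage 'simulate/extract' failed: {exc}") from exc

    try:
        split = selection.split_cohort(meta["stage_label"],
                                       config.phantom.train_fraction,
                                       seed=config.stage_seed("split"))
    except Exception as exc:
        raise StageError(f"stage 'split' failed: {exc}") from exc
    cohort = meta.copy()
    cohort["split"] = split

    selections: dict[str, selection.SelectionResult] = {}
    models: dict[str, staging.StageModel] = {}
    reports: dict[str, dict[str, staging.DiagnosticReport]] = {}
    correlations: dict[str, pd.DataFrame] = {}
    labels = cohort["stage_label"]
    for mod in MODALITIES:
        try:
            cleaned = selection.clean_features(feat_tables[mod], split)
            train = cleaned.train_rows(split)
            y_train = labels.reindex(train.index)
            ranking = selection.mrmr_rank(train, y_train,
                                          keep=config.mrmr_keep)
            kept = ranking["feature"].tolist()
            sel = selection.lasso_select(
                train[kept], y_train, folds=config.cv_folds,
                n_lambda=config.n_lambda,
                seed=config.stage_seed(f"lasso-{mod}"),
                mrmr_ranking=ranking)
            selections[mod] = sel
            if not sel.selected_features:
                raise RuntimeError("LASSO selected no feature")
        except Exception as exc:
            raise StageError(f"stage 'select-{mod}' failed: {exc}") from exc
        try:
            X_sel = cleaned.table[sel.selected_features]
            model = staging.fit_logistic(X_sel.loc[train.index], y_train,
                                         modality=mod)
            train_report = staging.evaluate(
                model, X_sel.loc[train.index], labels, cohort="train",
                calibration_bins=config.calibration_bins)
            model = model.with_cutoff(train_report.cohort_cutoff)
            test_idx = split[split == "test"].index
            test_report = staging.evaluate(
                model, X_sel.loc[test_idx], labels, cohort="test",
                cutoff=model.cutoff,
                calibration_bins=config.calibration_bins)
            models[mod] = model
            reports[mod] = {"train": train_report, "test": test_report}
        except Exception as exc:
            raise StageError(f"stage 'model-{mod}' failed: {exc}") from exc
        try:
            correlations[mod] = assoc.pearson_matrix(
                feat_tables[mod][sel.selected_features], met)
        except Exception as exc:
            raise StageError(f"stage 'correlate-{mod}' failed: {exc}") from exc

    try:
        comparison = assoc.compare_cohorts(cohort, met).table
    except Exception as exc:
        raise StageError(f"stage 'cohort-comparison' failed: {exc}") from exc

    manifest = _build_manifest(config, cohort, feat_tables, met, selections,
                               models, reports, correlations, comparison, out)
    return PipelineResult(cohort, feat_tables, met, selections, models,
                          reports, correlations, comparison, manifest)


def _report_dict(r: staging.DiagnosticReport) -> dict:
    return {"cohort": r.cohort, "auc": r.auc, "accuracy": r.accuracy,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "cutoff": r.cutoff, "cohort_cutoff": r.cohort_cutoff,
            "calibration_slope": r.calibration_slope,
            "calibration_intercept": r.calibration_intercept}


def _build_manifest(config, cohort, feat_tables, met, selections, models,
                    reports, correlations, comparison, out: str | None) -> dict:
    artifacts: dict[str, bytes] = {"cohort.csv": _csv_bytes(cohort)}
    for mod in MODALITIES:
        artifacts[f"features_{mod}.csv"] = _csv_bytes(feat_tables[mod])
        artifacts[f"correlations_{mod}.csv"] = _csv_bytes(correlations[mod]
                                                          .rename_axis("feature"))
        sel_json = json.dumps(selections[mod].to_dict(), sort_keys=True,
                              default=float).encode()
        artifacts[f"selection_{mod}.json"] = sel_json
        model = models[mod]
        model_json = json.dumps({
            "modality": mod, "intercept": model.intercept,
            "cutoff": model.cutoff,
            "coefficients": model.coefficients.to_dict()},
            sort_keys=True, default=float).encode()
        artifacts[f"model_{mod}.json"] = model_json
        rep_json = json.dumps({c: _report_dict(r)
                               for c, r in reports[mod].items()},
                              sort_keys=True, default=float).encode()
        artifacts[f"report_{mod}.json"] = rep_json
        for cohort_name, rep in reports[mod].items():
            artifacts[f"roc_{mod}_{cohort_name}.csv"] = _csv_bytes(
                rep.roc_points.rename_axis("point"))
            artifacts[f"calibration_{mod}_{cohort_name}.csv"] = _csv_bytes(
                rep.calibration_bins.rename_axis("row"))
    artifacts["metabolics.csv"] = _csv_bytes(met)
    artifacts["cohort_comparison.csv"] = _csv_bytes(
        comparison.rename_axis("row"))

    config_json = json.dumps(config.to_dict(), sort_keys=True,
                             default=float).encode()
    manifest = {
        "config_sha256": _sha256(config_json),
        "outputs": {name: _sha256(data)
                    for name, data in sorted(artifacts.items())},
    }
    if out:
        for name, data in artifacts.items():
            with open(os.path.join(out, name), "wb") as fh:
                fh.write(data)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        config.to_yaml(os.path.join(out, "config.yaml"))
    return manifest
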