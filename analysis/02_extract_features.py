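"""Preprocess the cohort and extract the 396-feature radiomics catalog.

Each subject's PET and MR volumes are resampled to 1 mm isotropic, grey
levels are normalized to 0-255, and the full histogram / shape / Haralick /
GLCM / RLM catalog is extracted over the anatomical lesion mask.  Writes one
feature table per modality (rows = subjects, columns = catalog names).
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from radstage import preprocessing as pp, texture as tx
from radstage.pipeline import RunConfig
from radstage.synthetic import iter_cohort

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cfg = RunConfig(seed=1)
    rows = {"pet": [], "mr": []}
    for rec in iter_cohort(cfg.phantom):
        mask = pp.resample_mask(rec.lesion_mask, cfg.target_spacing_mm)
        for mod, vol in (("pet", rec.pet_volume), ("mr", rec.mr_volume)):
            iso = pp.resample_isotropic(vol, cfg.target_spacing_mm)
            vec = tx.extract_all(pp.normalize_grey(iso), mask,
                                 levels=cfg.grey_levels, offsets=cfg.offsets)
            vec.name = rec.subject_id
            rows[mod].append(vec)
    os.makedirs(RESULTS, exist_ok=True)
    for mod in ("pet", "mr"):
        table = pd.DataFrame(rows[mod]).rename_axis("subject_id")
        path = os.path.join(RESULTS, f"features_{mod}.csv")
        table.to_csv(path)
        print(f"{mod.upper()}: {table.shape[0]} subjects x "
              f"{table.shape[1]} features -> {path}")


if __name__ == "__main__":
    main()
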