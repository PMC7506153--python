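"""Select staging features: cleaning, mRMR ranking, LASSO selection.

Per modality: training-set outlier replacement and standardization, greedy
mRMR down to 20 candidates, then an L1-penalized logistic path whose
penalty is chosen by 10-fold cross-validated misclassification error.
Writes the cleaned tables and a selection report per modality.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from radstage.io import read_table
from radstage.pipeline import RunConfig
from radstage.selection import clean_features, lasso_select, mrmr_rank

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cfg = RunConfig(seed=1)
    cohort = read_table(os.path.join(RESULTS, "cohort.csv"))
    split, labels = cohort["split"], cohort["stage_label"]
    for mod in ("pet", "mr"):
        feats = read_table(os.path.join(RESULTS, f"features_{mod}.csv"))
        cleaned = clean_features(feats, split)
        cleaned.table.to_csv(os.path.join(RESULTS, f"cleaned_{mod}.csv"))
        train = cleaned.train_rows(split)
        y = labels.reindex(train.index)
        ranking = mrmr_rank(train, y, keep=cfg.mrmr_keep)
        sel = lasso_select(train[ranking["feature"].tolist()], y,
                           folds=cfg.cv_folds, n_lambda=cfg.n_lambda,
                           seed=cfg.stage_seed(f"lasso-{mod}"),
                           mrmr_ranking=ranking)
        with open(os.path.join(RESULTS, f"selection_{mod}.json"), "w") as fh:
            json.dump(sel.to_dict(), fh, indent=2, default=float)
        print(f"\n{mod.upper()}: mRMR kept {len(ranking)}; LASSO selected "
              f"{len(sel.selected_features)} at lambda* = "
              f"{sel.lambda_star:.4g}:")
        for name in sel.selected_features:
            print(f"  {name}  (beta = {sel.coefficients[name]:+.3f})")


if __name__ == "__main__":
    main()
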