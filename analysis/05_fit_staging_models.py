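"""Fit the logistic staging models and evaluate them per cohort.

An unpenalized logistic regression on the selected standardized features
yields the per-subject radscore; the training cohort fixes the Youden
cutoff used for the headline test-set metrics.  Writes the diagnostic
reports plus ROC and calibration tables (and plots when matplotlib is
available).
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from radstage.io import read_table
from radstage.pipeline import RunConfig
from radstage.staging import evaluate, fit_logistic

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def _plot(mod, reports) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for cohort, rep in reports.items():
        axes[0].plot(rep.roc_points["fpr"], rep.roc_points["tpr"],
                     label=f"{cohort} (AUC {rep.auc:.2f})")
        axes[1].plot(rep.calibration_bins["mean_predicted"],
                     rep.calibration_bins["observed"], "o-", label=cohort)
    axes[0].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[0].set(xlabel="1 - specificity", ylabel="sensitivity",
                title=f"{mod.upper()} ROC")
    axes[1].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[1].set(xlabel="predicted probability", ylabel="observed fraction",
                title=f"{mod.upper()} calibration")
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(RESULTS, f"model_{mod}.png"), dpi=120)
    plt.close(fig)


def main() -> None:
    cfg = RunConfig(seed=1)
    cohort = read_table(os.path.join(RESULTS, "cohort.csv"))
    split, labels = cohort["split"], cohort["stage_label"]
    for mod in ("pet", "mr"):
        cleaned = read_table(os.path.join(RESULTS, f"cleaned_{mod}.csv"))
        with open(os.path.join(RESULTS, f"selection_{mod}.json")) as fh:
            selected = json.load(fh)["selected_features"]
        X = cleaned[selected]
        train_idx = split[split == "train"].index
        test_idx = split[split == "test"].index
        model = fit_logistic(X.loc[train_idx], labels, modality=mod)
        train_rep = evaluate(model, X.loc[train_idx], labels, cohort="train",
                             calibration_bins=cfg.calibration_bins)
        model = model.with_cutoff(train_rep.cohort_cutoff)
        test_rep = evaluate(model, X.loc[test_idx], labels, cohort="test",
                            cutoff=model.cutoff,
                            calibration_bins=cfg.calibration_bins)
        reports = {"train": train_rep, "test": test_rep}
        with open(os.path.join(RESULTS, f"model_{mod}.json"), "w") as fh:
            json.dump({"intercept": model.intercept,
                       "coefficients": model.coefficients.to_dict(),
                       "cutoff": model.cutoff}, fh, indent=2, default=float)
        print(f"\n{mod.upper()} staging model "
              f"(radscore cutoff {model.cutoff:.3f}):")
        for name, rep in reports.items():
            rep.roc_points.to_csv(
                os.path.join(RESULTS, f"roc_{mod}_{name}.csv"), index=False)
            rep.calibration_bins.to_csv(
                os.path.join(RESULTS, f"calibration_{mod}_{name}.csv"),
                index=False)
            print(f"  {name}: AUC {rep.auc:.3f}, accuracy {rep.accuracy:.2f},"
                  f" sensitivity {rep.sensitivity:.2f},"
                  f" specificity {rep.specificity:.2f}"
                  f" (own cutoff {rep.cohort_cutoff:.3f})")
        _plot(mod, reports)


if __name__ == "__main__":
    main()
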