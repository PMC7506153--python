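"""Correlate the selected radiomic features with PET metabolic parameters.

Pearson correlations of each modality's selected features — plus the
co-occurrence entropy feature tracked throughout the study — against
SUVmax, MTV and TLG over the full cohort, with */** significance flags.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from radstage.assoc import pearson_matrix
from radstage.io import read_table

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
TRACKED = "GLCMEntropy_angle0_offset4"


def main() -> None:
    met = read_table(os.path.join(RESULTS, "metabolics.csv"))
    for mod in ("pet", "mr"):
        feats = read_table(os.path.join(RESULTS, f"features_{mod}.csv"))
        with open(os.path.join(RESULTS, f"selection_{mod}.json")) as fh:
            selected = json.load(fh)["selected_features"]
        cols = list(dict.fromkeys(selected + [TRACKED]))
        table = pearson_matrix(feats[cols], met)
        table.rename_axis("feature").to_csv(
            os.path.join(RESULTS, f"correlations_{mod}.csv"))
        show = table[[c for c in table.columns
                      if c.startswith(("r_", "sig_"))]].copy()
        print(f"\n{mod.upper()} features vs metabolic parameters:")
        print(show.round(2).to_string())


if __name__ == "__main__":
    main()
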