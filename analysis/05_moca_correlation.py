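"""Correlation of the MoCA cognitive score with global alpha PLI, per group.

Pearson r with the t-transform p-value, computed separately within the
patient and control groups (the patient-group association is the planted,
cognitively meaningful one).  Needs results from steps 01-02.
"""

from pathlib import Path

import pandas as pd

from plimci.stats import pearson_correlation

REPO = Path(__file__).resolve().parents[1]
OUT = REPO / "results"


def main() -> None:
    table = pd.read_csv(OUT / "cohort.csv")
    features = pd.read_csv(OUT / "subject_features.csv")
    merged = table.merge(features, on="subject_id")
    rows = []
    for group in ("MCI", "NC"):
        sub = merged[merged.group == group]
        res = pearson_correlation(sub.global_pli_alpha, sub.moca)
        rows.append({"group": group, "r": res.statistic, "p": res.p_value,
                     "n": res.n})
        print(f"{group}: r = {res.statistic:.4f}, p = {res.p_value:.4f} "
              f"(n = {res.n})")
    pd.DataFrame(rows).to_csv(OUT / "moca_correlation.csv", index=False,
                              float_format="%.10g")
    print(f"wrote {OUT / 'moca_correlation.csv'}")


if __name__ == "__main__":
    main()
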