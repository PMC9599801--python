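"""Group comparisons: clinical table, band-wise global PLI, and the eight
named alpha electrode pairs.

Needs results/cohort.csv and results/subject_features.csv from the earlier
steps.  Also validates the printed clinical-table statistics (the fixed
desk check that needs no simulation).
"""

import json
from pathlib import Path

import pandas as pd

from plimci.montage import NAMED_PAIRS
from plimci.pipeline import validate_table1
from plimci.stats import rank_sum_test

REPO = Path(__file__).resolve().parents[1]
OUT = REPO / "results"


def main() -> None:
    print("printed clinical-table check:",
          json.dumps(validate_table1()["checks"], indent=2))

    table = pd.read_csv(OUT / "cohort.csv")
    features = pd.read_csv(OUT / "subject_features.csv")
    merged = table.merge(features, on="subject_id")
    mci = merged[merged.group == "MCI"]
    nc = merged[merged.group == "NC"]

    rows = []
    for band in ("delta", "theta", "alpha", "beta"):
        col = f"global_pli_{band}"
        res = rank_sum_test(mci[col], nc[col], method="asymptotic")
        rows.append({"band": band, "mean_MCI": mci[col].mean(),
                     "mean_NC": nc[col].mean(), "z": res.statistic, "p": res.p_value})
        print(f"{band:>5}: MCI {mci[col].mean():.3f} vs NC {nc[col].mean():.3f} "
              f"(z = {res.statistic:+.2f}, p = {res.p_value:.4f})")
    pd.DataFrame(rows).to_csv(OUT / "global_pli_by_band.csv", index=False,
                              float_format="%.10g")

    pair_rows = []
    for a, b in NAMED_PAIRS:
        col = f"pli_{a}_{b}"
        if col not in merged.columns:
            continue
        res = rank_sum_test(mci[col], nc[col], method="asymptotic")
        pair_rows.append({"pair": f"{a}-{b}", "mean_MCI": mci[col].mean(),
                          "mean_NC": nc[col].mean(), "z": res.statistic,
                          "p": res.p_value})
    pd.DataFrame(pair_rows).to_csv(OUT / "alpha_pairs.csv", index=False,
                                   float_format="%.10g")
    print(f"wrote band and pair comparisons to {OUT}")


if __name__ == "__main__":
    main()
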