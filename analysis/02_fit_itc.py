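"""Estimate discount rates and LL-reward sensitivities for the cohort.

Reads scratch/cohort/choices.csv, runs the logistic indifference-point fit
with mono-choice/inconsistent imputation, flags pooled extreme outliers, and
writes results/estimates.csv.  Prints the per-group summary the group tests
build on.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from itcmed.estimation import estimate_participants, remove_extreme_outliers

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    choices = pd.read_csv(ROOT / "scratch" / "cohort" / "choices.csv")
    est = estimate_participants(choices)

    # pooled 3*IQR fences, once per variable per reward type
    for col in ("log_k", "beta_amount"):
        for reward, sub in est.groupby("reward_type"):
            _, removed = remove_extreme_outliers(sub[col].to_numpy())
            if len(removed):
                ids = sub.iloc[removed]["participant_id"].tolist()
                print(f"outliers removed for {col}/{reward}: {ids}")
                est.loc[sub.index[removed], col] = np.nan

    est.to_csv(ROOT / "results" / "estimates.csv", index=False)
    for (g, reward), sub in est.groupby(["group", "reward_type"]):
        lk = sub["log_k"].dropna()
        print(f"{g:8s} {reward:6s} log k: mean {lk.mean():6.2f} (SD {lk.std():.2f}), "
              f"median {lk.median():6.2f} -> k = {np.exp(lk.median()):.2f}; "
              f"sensitivity mean {sub['beta_amount'].mean():+.3f}")
    counts = est[est["method"] != "logistic_fit"].groupby(
        ["group", "reward_type", "method"]).size()
    print("\nimputed estimates:")
    print(counts.to_string() if len(counts) else "  none")


if __name__ == "__main__":
    main()
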