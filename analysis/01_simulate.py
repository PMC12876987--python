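"""Generate the synthetic study cohort.

Simulates 22 bvFTD patients and 17 controls: 32-trial intertemporal-choice
tables for money and food rewards, clinical scores copula-linked to latent
impatience, and grey-matter-density volumes with planted atrophy and
behaviour coupling.  Raw cohort tables (CSV) go to scratch/cohort/; volumes (binary NIfTI) to
scratch/cohort_volumes/; both are regenerated on demand.
"""

from pathlib import Path

import numpy as np

from itcmed.pipeline import simulate_study
from itcmed.cohort import CohortSpec
from itcmed.volumes import VolumeSpec, save_cohort_niftis, save_truth

SEED = 20260922
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort = CohortSpec(seed=SEED)
    volume = VolumeSpec(seed=SEED)
    sim = simulate_study(cohort, volume, seed=SEED)

    sim["choices"].to_csv(out / "choices.csv", index=False)
    sim["clinical"].to_csv(out / "clinical.csv", index=False)
    save_truth(out, sim["truth"], sim["truth_maps"], volume)
    save_cohort_niftis(ROOT / "scratch" / "cohort_volumes", sim["volumes"],
                       sim["truth"], volume)

    truth = sim["truth"]
    print(f"cohort: {(truth['group'] == 'bvftd').sum()} bvFTD, "
          f"{(truth['group'] == 'control').sum()} controls")
    for g in ("bvftd", "control"):
        sub = truth[truth["group"] == g]
        print(f"  {g}: true log k (money) mean {sub['log_k_money'].mean():.2f} "
              f"(SD {sub['log_k_money'].std():.2f}); responder classes: "
              f"{sub['responder_class'].value_counts().to_dict()}")
    print(f"choice table: {len(sim['choices'])} rows "
          f"({sim['choices']['participant_id'].nunique()} participants x 2 rewards x 32 trials)")
    print(f"volumes: {sim['volumes'].shape}, mask {int(sim['mask'].sum())} voxels")


if __name__ == "__main__":
    main()
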