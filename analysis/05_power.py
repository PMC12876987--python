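"""Power arithmetic for the study design.

Two computations: (1) empirical power of the two-sided Wilcoxon rank-sum
test at the study's sample sizes (22 vs 16) under a strong expected effect,
P(X > Y) = 0.76; (2) the post-hoc mediation effect-size conversion
r = Z / sqrt(Z^2 + df) at df = 36 for representative path-a and path-b
Z values.  Writes results/power.json.
"""

import json
from pathlib import Path

from itcmed.stats import mediation_power_r, wilcoxon_power_sim

SEED = 20260922
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = wilcoxon_power_sim(n1=22, n2=16, p_xy=0.76, alpha=0.05,
                             reps=10_000, seed=SEED)
    print(f"Wilcoxon power at n=22 vs 16, P(X>Y)=0.76: {res.power:.1%} "
          f"({res.reps} replications)")
    conversions = {f"Z={z}": mediation_power_r(z, 36) for z in (0.04, 3.67)}
    for k, v in conversions.items():
        print(f"mediation effect size r at {k}, df=36: {v:.3f}")
    out = {"wilcoxon_power": res.power, "n1": res.n1, "n2": res.n2,
           "p_xy": res.p_xy, "alpha": res.alpha, "reps": res.reps,
           "effect_size_conversions_df36": conversions}
    (ROOT / "results" / "power.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
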