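"""Energy-deprivation kinetics: onsets, decay rates and recovery.

Simulates replicate nerves under glucose deprivation (GD), mitochondrial
blockade (MB) and their combination (MB+GD), extracts the ATP and CAP
kinetic parameters, and reproduces the associated comparisons: decay
onsets per condition (ANOVA + Newman-Keuls), equality of ATP and CAP
maximal decay rates under MB+GD (paired t), and the ordering of CAP vs
ATP recovery after reperfusion.

Writes results/deprivation_kinetics.csv and results/deprivation_stats.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from axatp.stats import GroupTable, anova_nk, paired_t, welch_t
from axatp.workflows import deprivation_kinetics, replicate_seeds, run

OUT = Path(__file__).resolve().parent.parent / "results"
N = 10


def main() -> None:
    seeds = replicate_seeds(2025, N)
    rows = []
    for name in ("GD", "MB", "MBGD"):
        for s in seeds:
            kin = deprivation_kinetics(run(name, seed=s))
            rows.append({"condition": name, "seed": s, **kin})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "deprivation_kinetics.csv", index=False)

    stats: dict = {}
    onset_groups = [GroupTable(c, df.loc[df.condition == c, "atp_onset_min"].to_numpy())
                    for c in ("GD", "MB", "MBGD")]
    stats["atp_onset_anova_nk"] = anova_nk(onset_groups)

    mbgd = df[df.condition == "MBGD"]
    t, dfree, p = paired_t(mbgd["atp_max_decay_rate"], mbgd["cap_max_decay_rate"])
    stats["mbgd_atp_vs_cap_decay_rate_paired_t"] = {"t": t, "df": dfree, "p": p}

    gd = df[df.condition == "GD"]
    t, dfree, p = welch_t(gd["cap_recovery_onset_s"], gd["atp_recovery_onset_s"])
    stats["gd_cap_vs_atp_recovery_onset_welch"] = {"t": t, "df": dfree, "p": p}

    with open(OUT / "deprivation_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)

    for c in ("GD", "MB", "MBGD"):
        sub = df[df.condition == c]
        print(f"{c:5s} ATP onset {sub.atp_onset_min.mean():6.2f} min  "
              f"CAP onset {sub.cap_onset_min.mean():6.2f} min  "
              f"ATP rate {sub.atp_max_decay_rate.mean():.4f}/s  "
              f"recovery onset ATP {sub.atp_recovery_onset_s.mean():5.1f} s, "
              f"CAP {sub.cap_recovery_onset_s.mean():5.1f} s")
    print("\nonset ordering GD > MB > MBGD; slowest decay induction under GD")
    print(f"MB+GD max decay rates: ATP {mbgd.atp_max_decay_rate.mean():.4f}/s vs "
          f"CAP {mbgd.cap_max_decay_rate.mean():.4f}/s, same order of magnitude "
          f"(paired p = {stats['mbgd_atp_vs_cap_decay_rate_paired_t']['p']:.2g}; "
          "simulated replicates share one nerve model, so this test sees only "
          "measurement noise and is far more sensitive than a between-animal test)")
    print(f"GD recovery: CAP precedes ATP in "
          f"{np.mean(gd['cap_recovery_onset_s'] < gd['atp_recovery_onset_s']):.0%} of nerves")


if __name__ == "__main__":
    main()
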