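#!/usr/bin/env python
"""Optogenetic reversal analysis: light-evoked reversals before and after conditioning.

Simulates 7 trials x 20 animals per group under the 10-pulse light schedule,
detects reversal onsets from the centroid tracks, computes the per-pulse
during-minus-after statistic over pulses 6-10, and compares the trial groups
with a Welch t-test.  The conditioned group's light-evoked rate increase is
abolished by construction.
"""

from pathlib import Path

import pandas as pd

from wormlearn import pipeline

SEED = 20260105
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = pipeline.reversal_stage(seed=SEED)
    trials = pd.DataFrame(
        [
            {"group": g, "trial_id": s.trial_id, "n_animals": s.n_animals,
             "during_minus_after": s.during_minus_after}
            for g in ("naive", "conditioned")
            for s in res["groups"][g]
        ]
    )
    trials.to_csv(OUT / "reversal_trials.csv", index=False)
    for g, tc in res["timecourses"].items():
        tc.to_csv(OUT / f"reversal_timecourse_{g}.csv", index=False)
    t = res["test"]
    pd.DataFrame([{"t": t.statistic, "df": t.df, "p": t.p}]).to_csv(
        OUT / "reversal_test.csv", index=False
    )

    print("trial-level during-minus-after (mean per pulse, summed over animals):")
    print(trials.groupby("group")["during_minus_after"].agg(["mean", "std", "count"]))
    print(f"\nWelch t-test naive vs conditioned: t={t.statistic:.2f}, "
          f"df={t.df:.1f}, p={t.p:.2g} ({t.tier()})")
    print("=> light evokes extra reversals in naive trials only.")


if __name__ == "__main__":
    main()
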