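#!/usr/bin/env python
"""EGL-4 nuclear-enrichment analysis on synthetic cell images.

Quantifies the nuclear index (mean nuclear / mean cytoplasmic fluorescence)
in 80 cells per condition, where the conditioned population is a 50:50
mixture in which only the AWC-ON-like half shifts its index from 1.0 to 1.5,
and compares the cumulative distributions with a two-sample
Kolmogorov-Smirnov test.
"""

from pathlib import Path

import pandas as pd

from wormlearn import pipeline

SEED = 20260103
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = pipeline.nuclear_stage(seed=SEED)
    res["records"].to_csv(OUT / "nuclear_indices.csv", index=False)
    pd.DataFrame([{"ks_D": res["D"], "ks_p": res["p"]}]).to_csv(
        OUT / "nuclear_ks.csv", index=False
    )
    med = res["records"].groupby("condition")["nuclear_index"].median()
    print("median nuclear index per condition:")
    print(med.to_string())
    print(f"\ntwo-sample KS: D={res['D']:.3f}, p={res['p']:.2g}")
    print("=> the conditioned distribution is right-shifted even though only "
          "half its cells (the AWC-ON-like half) translocate.")


if __name__ == "__main__":
    main()
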