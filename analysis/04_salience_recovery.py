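#!/usr/bin/env python
"""Check that the salience analysis recovers the generator's ground truth.

Simulates single-locality surveys (40 informants, 100 taxa) across a grid
of Zipf exponents and reports the Spearman correlation between the true
salience ranking and the rankings implied by Smith's S and by citation
frequency. At the reference exponent s = 1.2 the Smith's S correlation
should clear 0.8; at s = 0 there is no salience signal to recover and the
correlation is reported without a threshold.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ethnolika import SyntheticSpec, generate, recover

OUT = Path(__file__).resolve().parents[1] / "results" / "recovery"


def main(n_seeds: int = 10) -> None:
    rows = []
    for s in (0.0, 0.6, 1.2, 2.0):
        for seed in range(n_seeds):
            spec = SyntheticSpec(localities={"A": 40}, n_taxa=100,
                                 zipf_s=s, rank_noise_sd=0.0, seed=seed)
            survey, truth = generate(spec)
            rep = recover(survey, truth)
            rows.append({"zipf_s": s, "seed": seed,
                         "spearman_sj": rep["spearman_sj"],
                         "spearman_fc": rep["spearman_fc"]})
    df = pd.DataFrame(rows)

    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "salience_recovery.csv", index=False)

    by_s = df.groupby("zipf_s")[["spearman_sj", "spearman_fc"]].mean()
    print("mean Spearman correlation with the true salience ranking:")
    print(by_s.round(3).to_string())
    at_ref = df[df["zipf_s"] == 1.2]["spearman_sj"]
    print(f"s = 1.2: Smith's S recovery {at_ref.mean():.3f} "
          f"(min over seeds {at_ref.min():.3f}; reference threshold 0.8)")
    print(f"wrote recovery table to {OUT}")


if __name__ == "__main__":
    main()
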