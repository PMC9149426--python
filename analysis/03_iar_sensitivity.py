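#!/usr/bin/env python
"""Probe the inhibitor additivity ratio as a specificity diagnostic.

Two in-memory experiments on 60-site denitrification transects with sites
held near the transect guild profile and 2% analytical noise: one with
perfectly specific inhibitors, one where the bactericide also suppresses 20%
of the fungal rate. A useful diagnostic keeps IAR inside [0.9, 1.1] in the
first case and pushes it outside in the second.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import guildflux as gf
from guildflux.io import rates_frame
from guildflux.kinetics import fit_rate
from guildflux.partition import compute_iar
from guildflux.pipeline import build_treatment_slopes

SEED = 1
OUT = Path("results/iar_sensitivity.csv")


def iar_values(cross_inhibition: dict, seed: int) -> np.ndarray:
    config = gf.SyntheticConfig(
        n_sites=60,
        assays=("denitrification",),
        noise_model="multiplicative",
        noise_cv=0.02,
        share_concentration=150.0,
        cross_inhibition=cross_inhibition,
        seed=seed,
    )
    truth = gf.draw_truth(config)
    series = gf.simulate_measurements(truth, config)
    rates = rates_frame(series, [fit_rate(s) for s in series], [True] * len(series))
    return np.array([compute_iar(s).iar for s in build_treatment_slopes(rates)])


def main() -> None:
    rows = []
    for label, cross in (
        ("specific", {}),
        ("cross_20pct_fungal", {"bactericide": {"fungal": 0.2}}),
    ):
        iars = iar_values(cross, SEED)
        inside = ((iars >= 0.9) & (iars <= 1.1)).mean()
        rows.append(
            {"scenario": label, "n_sites": len(iars), "iar_mean": iars.mean(),
             "iar_min": iars.min(), "iar_max": iars.max(),
             "fraction_in_band": inside}
        )
        print(
            f"{label}: mean IAR {iars.mean():.3f}, "
            f"{inside * 100:.0f}% of sites inside [0.9, 1.1]"
        )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"table -> {OUT}")


if __name__ == "__main__":
    main()
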