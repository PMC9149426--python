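#!/usr/bin/env python
"""Generate the synthetic grassland transect used by the downstream analyses.

Eight sites, two assays (nitrification and denitrification), six inhibitor
treatments (control, streptomycin, cycloheximide, combined, autoclaved,
simvastatin), four replicate bottles, sampled at 0/24/48 h. The raw bottle
table is large, so it lands under scratch/ (regenerate any time with the same
seed); the ground-truth sidecar records what the pipeline should recover.
"""

from pathlib import Path

import guildflux as gf

SEED = 20260922
DATA_DIR = Path("scratch/transect")


def main() -> None:
    config = gf.SyntheticConfig(seed=SEED, include_archaeal_inhibitor=True)
    paths = gf.generate_dataset(config, DATA_DIR)
    truth = gf.draw_truth(config)
    print(f"wrote synthetic transect to {DATA_DIR} (seed {SEED})")
    for assay in config.assays:
        shares = truth.pooled_contributions(assay)
        pretty = ", ".join(f"{g} {v:.0f}%" for g, v in shares.items())
        print(f"  ground-truth pooled {assay} contributions: {pretty}")
    print(f"  files: {', '.join(p.name for p in paths.values())}")


if __name__ == "__main__":
    main()
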