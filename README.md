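# guildflux

Soil produces N₂O through nitrification and denitrification carried out by
several microbial guilds at once — bacteria, fungi and archaea — plus a purely
abiotic component. Bulk potential-activity assays measure only the total.
`guildflux` implements the selective-inhibition incubation analysis that
splits the total into its guild components, for soil ecologists and
biogeochemists running (or simulating) inhibitor-difference assay campaigns.

## The method

Parallel slurry incubations of the same soil are run under a no-inhibitor
control, a bactericide (streptomycin), a fungicide (cycloheximide), both
inhibitors combined, an autoclave-sterilized treatment and, optionally, an
archaeal inhibitor (simvastatin). For each bottle, the enzyme activity *k*
(μg N g⁻¹ dry soil h⁻¹) is the OLS slope of product accumulation —
NO₂⁻ + NO₃⁻ for nitrification (NEA), N₂O under acetylene block for
denitrification (DEA) — over 0/24/48 h. Treatment differences give the
partition:

    TNEA = k(control)
    BNEA = TNEA − k(bactericide)
    FNEA = TNEA − k(fungicide)
    ANEA = TNEA − BNEA − FNEA − k(sterilized)
    abiotic = k(sterilized)

and identically TDEA/BDEA/FDEA/ADEA for denitrification. The raw components
sum to the total exactly. Inhibitor specificity is checked with the
inhibitor additivity ratio over the four-treatment set,

    IAR = [(A − B) + (A − C)] / (A − D),

which sits near 1 when the two inhibitors are specific and additive. The
archaeal estimate is cross-validated against the direct simvastatin method
(ANEA₂ = k(control) − k(simvastatin)) with a paired signed-rank test, and
functional-gene abundances (AOA/AOB amoA, narG, nirK, …) are regressed on
total and guild-matched activities.

Because campaigns of this kind rarely deposit raw bottle-level data, the
package ships a synthetic transect generator with known ground truth
(per-site guild rates, inhibitor efficiency matrix, measurement noise,
gene–guild coupling), so every stage is testable by parameter recovery.

## Worked example

```sh
python analysis/01_simulate_transect.py   # synthetic campaign -> scratch/transect
python analysis/02_run_pipeline.py        # full analysis -> results/pipeline
```

which prints:

```
  ground-truth pooled nitrification contributions: bacterial 19%, fungal 25%, archaeal 34%, abiotic 22%
  ground-truth pooled denitrification contributions: bacterial 15%, fungal 46%, archaeal 29%, abiotic 10%
  recovered pooled denitrification contributions: abiotic 9.4%, archaeal 30.8%, bacterial 14.5%, fungal 45.6%
  recovered pooled nitrification contributions: abiotic 22.0%, archaeal 34.1%, bacterial 19.0%, fungal 24.9%
  archaeal method check (denitrification): p = 0.945 (agree)
  archaeal method check (nitrification): p = 0.844 (agree)
```

The first two lines are the generator's ground truth — transect-pooled guild
shares of the total activity. The recovered lines come from running the
whole pipeline (slope fits, partition, pooled contribution summary) on the
noisy bottle-level measurements: each share lands within about one
percentage point of truth at the default noise level. The archaeal check
compares the four-treatment difference estimate with the direct simvastatin
estimate site by site; p > 0.05 means the two methods are statistically
indistinguishable. `analysis/03_iar_sensitivity.py` and
`analysis/04_gene_matched_correlations.py` probe the IAR diagnostic and the
gene-regression pattern (guild-matched r² exceeds total-activity r²).

The same steps are available as a CLI (`guildflux simulate`, `guildflux
run`, `guildflux report`, plus single-stage subcommands) for use on real
measurement tables; see `guildflux --help` for the file schemas accepted.

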