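# Methods

## Model and assumptions

The analysis treats each incubation bottle as accumulating product linearly
under substrate excess: amount(t) = k·t + b + ε, with the enzyme activity k
(μg N g⁻¹ dry soil h⁻¹) estimated by ordinary least squares over the
sampling times (default 0/24/48 h). Linearity is the operative assumption of
a *potential* assay — substrate is added in excess and the incubation is
short — and is guarded by an r² screen (`qc_linearity`, default threshold
0.9). A constant response has an undefined r² (0/0); it is reported missing
rather than 0 or 1, and passes QC only as a flat blank (k = 0), since a flat
series carries no evidence against linearity while a sloped fit must justify
itself.

The guild partition is pure difference algebra over treatment-mean slopes:

* total = k(control)
* bacterial = total − k(bactericide)
* fungal = total − k(fungicide)
* archaeal = total − bacterial − fungal − k(sterilized)
* abiotic = k(sterilized)

The archaeal line subtracts the bacterial and fungal *components of the same
assay* together with the sterilized slope — the parallel form used for both
assays. Raw components satisfy bacterial + fungal + archaeal + abiotic =
total exactly; this identity is asserted in tests to 1e-12. The design
assumes: (i) each inhibitor fully and exclusively suppresses its target
guild; (ii) sterilization removes all biotic activity while leaving abiotic
chemistry; (iii) inhibitors act additively. Assumption (i)/(iii) violations
are what the IAR = [(A−B)+(A−C)]/(A−D) diagnostic detects: with specific,
additive inhibitors the numerator and denominator both equal the combined
bacterial + fungal activity, so IAR = 1. The ratio is scale-invariant and
undefined when control equals the combined treatment (no removable biotic
signal — an error, not a 0/0 silently passed).

Implicit in subtracting per-treatment means is that bottles are exchangeable
across treatments: there is no pairing of replicate bottles between
treatments, which is why uncertainty is propagated by resampling replicates
independently *within* each treatment (bootstrap, SEM = SD of the bootstrap
component distribution) rather than by paired differences.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_r2` | 0.9 | linearity screen on per-bottle fits |
| `iar_band` | (0.9, 1.1) | acceptance band for inhibitor additivity |
| `contribution_mode` | pooled | transect aggregation (ratio of sums) |
| `total_floor` | 0.05 μg N g⁻¹ h⁻¹ | per-site-mean mode: sites below this total are excluded |
| `n_boot` | 1000 | bootstrap draws for SEMs and contribution CIs |
| `transform` | log10(copies+1) | gene-abundance transform before regression |

Pooled aggregation (guild share = Σ guild / Σ total across sites) is the
default because per-site ratios explode when a site's total approaches zero;
the per-site-mean alternative uses the floor above (the order of the
smallest total activities seen in comparable grassland surveys) and reports
which sites it excluded. Negative components — sampling noise or slight
over-inhibition — are clamped to 0 for reporting, with the raw value and a
flag always retained; contribution summaries use clamped values, so pooled
percentages can exceed 100 by the clamped mass (the clamp counts are in the
run log). The gene transform default keeps zero copy numbers in the
regression (abundances span 0 to ~10⁹ copies g⁻¹); a positive-only log and
an identity passthrough are available, and the choice is echoed into the
output metadata.

## The synthetic generator

The generator emulates a transect campaign: per site and assay, ground-truth
bacterial/fungal/archaeal/abiotic rates; an inhibition matrix E[treatment,
guild] (defaults: bactericide→bacteria 1.0, fungicide→fungi 1.0, combined
composes both, sterilization suppresses all biota, simvastatin→archaea 1.0,
cross-inhibition 0 but injectable); linear accumulation with per-measurement
noise; gene tables with log₁₀(copies) = α + β·(matched guild rate) + noise;
and a site covariate table. Defaults are the emulated study conditions:
8 sites × 2 assays × 5 treatments (6 with simvastatin) × 4 replicates,
times 0/24/48 h, lognormal site totals (median 0.6/0.8 μg N g⁻¹ h⁻¹ for
NEA/DEA, log-sd 0.9 — totals spanning roughly 0.1–4, the range seen in
temperate-to-alpine grassland soils), transect pooled guild shares of
19/25/34/22 % (bacterial/fungal/archaeal/abiotic) for nitrification and
15/46/29/10 % for denitrification. When a target share profile is set, the
realized draws are rescaled so the pooled shares match it exactly
(pre-noise), preserving the pooled total; this makes recovery tests sharp
rather than only correct in expectation.

Measurement noise is additive Gaussian, truncated at zero, default sd
1.0 μg N g⁻¹ per measurement; a multiplicative (relative) model is available
behind `noise_model`. Truncation at zero has one measurable side effect:
at t = 0 the clean amount is 0, so truncation lifts the expected reading by
σ/√(2π), which biases a single fitted slope down by about 0.0083·σ (the
t = 0 OLS weight times the lift). The bias is identical across treatments at
fixed σ, so it cancels from every component difference — only the total
carries it, at well below 1 % for default settings. Random streams are keyed
hierarchically (seed, site, replicate, assay, treatment), so enlarging the
design never perturbs existing draws.

What the generator does **not** emulate: substrate depletion or lag phases
(accumulation is exactly linear), partial acetylene block, inhibitor decay
over the incubation, spatial autocorrelation between sites, and qPCR
inhibition or primer-efficiency artifacts. Passing recovery tests therefore
demonstrates that the *estimator chain* is correct under the stated assay
model, not that the assay model holds in any particular soil.

## Numerical and design choices

* **Slope estimator.** Plain two-parameter OLS on all sampled points
  (`scipy.stats.linregress`), matched in tests against the closed-form
  formulas to 1e-10. No robust or weighted variant: three points cannot
  support one, and the assay's defense against curvature is the r² screen.
* **Slurry withdrawal correction.** Sampling removes 10 ml of an 80 ml
  slurry at each time point. The default conversion ignores this (the naive
  per-volume reading); an explicit mass-balance correction is available,
  taking (volume, concentration) pairs for prior withdrawals, because the
  removed N mass depends on the concentration at removal time.
* **Headspace N₂O.** Ideal gas law at the incubation temperature (301.15 K)
  and 1 atm unless overridden; 28.01 g N per mol N₂O. Dissolved N₂O is
  deliberately ignored — under acetylene block with shaking, the headspace
  holds the bulk of the N₂O and the dissolved fraction cancels from slope
  comparisons.
* **Archaeal cross-validation.** Default test is the signed-rank
  (Wilcoxon) on site-paired differences between the difference-method and
  simvastatin-method estimates — small n, no normality assumption; a paired
  t is available. All-zero differences short-circuit to p = 1 (the exact
  test is undefined there, and identical methods should read as agreement).
  Raw (unclamped) archaeal components are compared, since clamping would
  mask exactly the disagreements the check exists to find.
* **Ties and degenerates.** A constant gene predictor yields a flagged
  degenerate regression record (statistics missing) instead of an exception,
  so one flat gene does not abort a batch; an all-below-floor contribution
  request and a control-equals-combined IAR are errors, because the quantity
  is scientifically undefined rather than merely missing.
* **Determinism.** Every stochastic step (bootstraps, generator) takes an
  explicit seed; outputs carry no timestamps, and the run manifest records
  config, seed and SHA-256 checksums of inputs and outputs, so a rerun from
  the same inputs is byte-identical.

## Validation experiments shipped with the package

The acceptance suite fixes the following study conditions (chosen by
pre-experiment Monte-Carlo design, then frozen):

* **Noisy recovery** uses 8 denitrification sites × 4 replicates with the
  transect share profile above and additive noise sd 1.9 μg N g⁻¹ — 10 % of
  the median site's 24-h accumulation, the package's operational definition
  of "10 % measurement noise". A 200-run Monte-Carlo of this design gives a
  mean max-abs share error of 1.8 points, so the ±3-point check is a
  calibrated, non-trivial bound. Per-point *relative* 10 % noise is a
  strictly harsher regime: with three time points the middle point carries
  zero slope weight, so per-bottle slope error equals the full CV and the
  archaeal pooled share alone has an sd near 3.5 points at this design size.
* **IAR sensitivity** uses 60 denitrification sites held near the transect
  guild profile (Dirichlet concentration 150) with 2 % multiplicative
  analytical noise, probing the diagnostic against inhibitor specificity
  rather than site composition: with the default compositional spread, sites
  where bacteria rival fungi shift IAR by less than the band half-width
  under 20 % cross-inhibition, which is a property of those compositions,
  not of the statistic.

## Known limitations

* With only three time points, the linearity screen has little power; r²
  thresholds near 1 reject only gross curvature.
* Clamping makes reported contribution percentages sum to slightly more
  than 100 when components go negative; the raw, conservation-exact values
  are always in the partition table.
* The difference design attributes to "archaea" everything not removed by
  the bactericide, fungicide or sterilization — any unculled guild
  (e.g. comammox-like organisms) is folded into that remainder.
* Bootstrap SEMs with 3–4 replicates per treatment are themselves noisy;
  they quantify spread, not small-sample bias.
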