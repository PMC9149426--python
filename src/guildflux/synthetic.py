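"""Synthetic transect generator with known ground truth.

Emulates a selective-inhibition incubation campaign across a grassland
transect: per site and assay, ground-truth bacterial, fungal, archaeal and
abiotic rates; per treatment, an inhibition matrix giving the fraction of each
guild suppressed (streptomycin → bacteria, cycloheximide → fungi, autoclave →
all biota, simvastatin → archaea); linear product accumulation over 0/24/48 h
with additive or multiplicative measurement noise; qPCR gene tables whose
log10 copy numbers are linear in the matched guild's rate; and a site
covariate table. Random streams are keyed hierarchically (site, assay,
treatment, replicate), so adding replicates or treatments never perturbs
existing draws.

The truth sidecar is written next to the generated CSVs but is never read by
any analysis stage — recovery tests compare pipeline output against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .kinetics import IncubationSeries
from .partition import GUILDS

BIOTIC_GUILDS = ("bacterial", "fungal", "archaeal")

#: Transect-level contribution profiles (% of total) used as generator
#: defaults: fungi dominate, then archaea, then bacteria, with a small
#: abiotic remainder — the regime these grassland soils sit in.
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "nitrification": {"bacterial": 19.0, "fungal": 25.0, "archaeal": 34.0, "abiotic": 22.0},
    "denitrification": {"bacterial": 15.0, "fungal": 46.0, "archaeal": 29.0, "abiotic": 10.0},
}

#: Lognormal medians of site total activity (μg N g⁻¹ h⁻¹) per assay; with the
#: default spread the site totals span roughly 0.1–4, inside the field-typical
#: 0.03–4.8 range for temperate grassland soils.
DEFAULT_TOTAL_MEDIAN = {"nitrification": 0.6, "denitrification": 0.8}
DEFAULT_TOTAL_SIGMA = 0.9

_SITE_NAMES = (
    "site01", "site02", "site03", "site04", "site05", "site06", "site07", "site08",
)


@dataclass(frozen=True)
class GeneCoupling:
    """log10(copies) = alpha + beta * rate(assay, guild) + noise."""

    assay: str
    guild: str
    alpha: float
    beta: float
    sigma: float  # site-level coupling noise, log10 units


#: Marker genes coupled to the guild whose activity they should track; nirS
#: and the nosZ clades are coupled weakly (they sit downstream of the measured
#: N2O pool), and the fungal nirK assay yields nothing (emitted as absent).
DEFAULT_GENE_COUPLING: dict[str, GeneCoupling] = {
    "AOA": GeneCoupling("nitrification", "archaeal", 6.0, 3.0, 0.25),
    "AOB": GeneCoupling("nitrification", "bacterial", 5.5, 3.0, 0.25),
    "narG": GeneCoupling("denitrification", "bacterial", 5.0, 3.0, 0.25),
    "nirK": GeneCoupling("denitrification", "bacterial", 4.5, 3.0, 0.25),
    "nirS": GeneCoupling("denitrification", "bacterial", 4.0, 1.0, 0.6),
    "nosZ": GeneCoupling("denitrification", "bacterial", 5.0, 1.0, 0.6),
    "nosZII": GeneCoupling("denitrification", "bacterial", 5.5, 1.0, 0.6),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for a synthetic transect."""

    n_sites: int = 8
    n_replicates: int = 4
    times: tuple[float, ...] = (0.0, 24.0, 48.0)
    assays: tuple[str, ...] = ("nitrification", "denitrification")
    total_median: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOTAL_MEDIAN)
    )
    total_sigma: float = DEFAULT_TOTAL_SIGMA
    contribution_profile: Mapping[str, Mapping[str, float]] | None = field(
        default_factory=lambda: {a: dict(p) for a, p in DEFAULT_PROFILES.items()}
    )
    #: Dirichlet concentration controlling site-to-site spread of guild shares.
    share_concentration: float = 12.0
    bactericide_efficiency: float = 1.0
    fungicide_efficiency: float = 1.0
    simvastatin_specificity: float = 1.0
    #: Off-target suppression: {treatment: {guild: extra fraction}}.
    cross_inhibition: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_model: str = "additive"
    noise_sd: float = 1.0  # additive, μg N g⁻¹ per measurement
    noise_cv: float = 0.10  # multiplicative, relative sd per measurement
    include_archaeal_inhibitor: bool = False
    gene_coupling: Mapping[str, GeneCoupling] = field(
        default_factory=lambda: dict(DEFAULT_GENE_COUPLING)
    )
    gene_replicate_sigma: float = 0.1  # replicate-level qPCR noise, log10 units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidConfigError("n_sites must be >= 1")
        if self.n_replicates < 2:
            raise InvalidConfigError("n_replicates must be >= 2")
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidConfigError("times must start at 0 and strictly increase")
        if self.noise_model not in ("additive", "multiplicative"):
            raise InvalidConfigError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise InvalidConfigError("noise levels must be >= 0")
        if self.contribution_profile is not None:
            for assay, prof in self.contribution_profile.items():
                total = sum(prof.get(g, 0.0) for g in GUILDS)
                if total > 100.0 + 1e-9:
                    raise InvalidConfigError(
                        f"{assay} contribution profile sums to {total} > 100%"
                    )
                if total <= 0:
                    raise InvalidConfigError(f"{assay} contribution profile sums to 0")

    @property
    def treatments(self) -> tuple[str, ...]:
        base = ("control", "bactericide", "fungicide", "combined", "sterilized")
        if self.include_archaeal_inhibitor:
            return base + ("archaeal_inhibitor",)
        return base


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one synthetic transect."""

    site_ids: tuple[str, ...]
    #: rates[assay][guild] -> per-site array, μg N g⁻¹ h⁻¹.
    rates: Mapping[str, Mapping[str, np.ndarray]]
    #: inhibition[treatment][guild] -> suppressed fraction in [0, 1].
    inhibition: Mapping[str, Mapping[str, float]]
    noise_model: str
    noise_sd: float
    noise_cv: float
    gene_coupling: Mapping[str, GeneCoupling]
    gene_replicate_sigma: float
    seed: int

    def effective_rate(self, assay: str, site_index: int, treatment: str) -> float:
        """Expected product slope under a treatment: surviving biota + abiotic."""
        if treatment not in self.inhibition:
            raise InvalidInputError(f"unknown treatment {treatment!r}")
        supp = self.inhibition[treatment]
        r = self.rates[assay]
        biotic = sum(
            r[g][site_index] * (1.0 - supp.get(g, 0.0)) for g in BIOTIC_GUILDS
        )
        return float(biotic + r["abiotic"][site_index])

    def pooled_contributions(self, assay: str) -> dict[str, float]:
        """Ground-truth transect pooled guild shares, %."""
        r = self.rates[assay]
        total = sum(r[g].sum() for g in GUILDS)
        return {g: float(r[g].sum() / total * 100.0) for g in GUILDS}

    def to_jsonable(self) -> dict:
        return {
            "site_ids": list(self.site_ids),
            "rates": {
                a: {g: [float(v) for v in arr] for g, arr in guilds.items()}
                for a, guilds in self.rates.items()
            },
            "inhibition": {t: dict(g) for t, g in self.inhibition.items()},
            "noise_model": self.noise_model,
            "noise_sd": self.noise_sd,
            "noise_cv": self.noise_cv,
            "gene_coupling": {
                g: dataclasses.asdict(c) for g, c in self.gene_coupling.items()
            },
            "gene_replicate_sigma": self.gene_replicate_sigma,
            "seed": self.seed,
            "pooled_contributions": {
                a: self.pooled_contributions(a) for a in self.rates
            },
        }


def _rng(*key: int) -> np.random.Generator:
    """Keyed generator: independent stream per (seed, index...) tuple."""
    return np.random.default_rng([int(k) for k in key])


def _build_inhibition(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    bact = {"bacterial": config.bactericide_efficiency}
    fung = {"fungal": config.fungicide_efficiency}
    # Combined treatment composes the two inhibitors independently.
    combined = {g: 1.0 - (1.0 - bact.get(g, 0.0)) * (1.0 - fung.get(g, 0.0))
                for g in BIOTIC_GUILDS}
    combined = {g: v for g, v in combined.items() if v > 0}
    inhibition: dict[str, dict[str, float]] = {
        "control": {},
        "bactericide": dict(bact),
        "fungicide": dict(fung),
        "combined": combined,
        "sterilized": {g: 1.0 for g in BIOTIC_GUILDS},
        "archaeal_inhibitor": {"archaeal": config.simvastatin_specificity},
    }
    for treatment, extra in config.cross_inhibition.items():
        if treatment not in inhibition:
            raise InvalidConfigError(f"cross_inhibition names unknown treatment {treatment!r}")
        for guild, frac in extra.items():
            if guild not in BIOTIC_GUILDS:
                raise InvalidConfigError(f"cross_inhibition names unknown guild {guild!r}")
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError("cross-inhibition fractions must be in [0, 1]")
            base = inhibition[treatment].get(guild, 0.0)
            inhibition[treatment][guild] = min(1.0, 1.0 - (1.0 - base) * (1.0 - frac))
    # Combined inherits any off-target terms of its two constituents.
    for guild in BIOTIC_GUILDS:
        b = inhibition["bactericide"].get(guild, 0.0)
        f = inhibition["fungicide"].get(guild, 0.0)
        composed = 1.0 - (1.0 - b) * (1.0 - f)
        if composed > inhibition["combined"].get(guild, 0.0):
            inhibition["combined"][guild] = composed
    return inhibition


def draw_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw per-site guild rates; deterministic given the config seed.

    Site totals are lognormal; guild shares are Dirichlet around the target
    profile. When a contribution profile is set, each guild's rates are then
    rescaled so the realized transect pooled shares equal the profile exactly
    (normalized to its own sum) — the generator's headline contract, checked
    pre-noise to 1e-9.
    """
    site_ids = tuple(
        _SITE_NAMES[i] if i < len(_SITE_NAMES) else f"site{i + 1:02d}"
        for i in range(config.n_sites)
    )
    rates: dict[str, dict[str, np.ndarray]] = {}
    for ai, assay in enumerate(config.assays):
        rng = _rng(config.seed, 101, ai)
        median = float(config.total_median[assay])
        totals = np.exp(rng.normal(np.log(median), config.total_sigma, config.n_sites))
        profile = None
        if config.contribution_profile is not None:
            profile = config.contribution_profile.get(assay)
        if profile is None:
            base = np.full(len(GUILDS), 25.0)
        else:
            base = np.array([profile.get(g, 0.0) for g in GUILDS])
            base = base / base.sum() * 100.0
        if np.isfinite(config.share_concentration):
            alpha = np.maximum(base / 100.0 * config.share_concentration, 1e-3)
            shares = rng.dirichlet(alpha, size=config.n_sites)  # sites × guilds
        else:
            # Infinite concentration: every site at exactly the profile shares.
            shares = np.tile(base / 100.0, (config.n_sites, 1))
        raw = shares * totals[:, None]
        if profile is not None:
            # Exact pooled-share calibration preserving the transect total.
            pooled_total = raw.sum()
            col_sums = raw.sum(axis=0)
            scale = (base / 100.0) * pooled_total / col_sums
            raw = raw * scale[None, :]
        rates[assay] = {g: raw[:, j].copy() for j, g in enumerate(GUILDS)}
    return SyntheticTruth(
        site_ids=site_ids,
        rates=rates,
        inhibition=_build_inhibition(config),
        noise_model=config.noise_model,
        noise_sd=config.noise_sd,
        noise_cv=config.noise_cv,
        gene_coupling=dict(config.gene_coupling),
        gene_replicate_sigma=config.gene_replicate_sigma,
        seed=config.seed,
    )


def simulate_timecourse(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    site_index: int,
    treatment: str,
    assay: str,
    replicate_index: int,
) -> IncubationSeries:
    """One bottle's noisy time course under one treatment."""
    assays = list(config.assays)
    rate = truth.effective_rate(assay, site_index, treatment)
    t = np.asarray(config.times)
    clean = rate * t
    rng = _rng(
        truth.seed, 202, site_index, replicate_index,
        assays.index(assay), list(truth.inhibition).index(treatment),
    )
    if truth.noise_model == "additive":
        noisy = clean + rng.normal(0.0, truth.noise_sd, len(t)) if truth.noise_sd > 0 else clean
    else:
        noisy = clean * (1.0 + rng.normal(0.0, truth.noise_cv, len(t))) if truth.noise_cv > 0 else clean
    noisy = np.maximum(noisy, 0.0)
    return IncubationSeries(
        site_id=truth.site_ids[site_index],
        replicate_id=f"rep{replicate_index + 1}",
        assay=assay,
        treatment=treatment,
        times=tuple(float(x) for x in t),
        amounts=tuple(float(x) for x in noisy),
    )


def simulate_measurements(truth: SyntheticTruth, config: SyntheticConfig) -> list[IncubationSeries]:
    """All bottles for the full design: sites × assays × treatments × replicates."""
    out = []
    for si in range(config.n_sites):
        for assay in config.assays:
            for treatment in config.treatments:
                for ri in range(config.n_replicates):
                    out.append(
                        simulate_timecourse(truth, config, si, treatment, assay, ri)
                    )
    return out


def simulate_genes(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """qPCR gene table: log10 copies linear in the matched guild rate.

    The fungal nirK assay fails in these soils, so FnirK is emitted as absent
    (no rows) rather than as zeros.
    """
    rows = []
    for gi, (gene, cpl) in enumerate(sorted(config.gene_coupling.items())):
        if cpl.assay not in truth.rates:
            continue
        guild_rate = truth.rates[cpl.assay][cpl.guild]
        rng = _rng(truth.seed, 303, gi)
        site_log10 = cpl.alpha + cpl.beta * guild_rate
        if cpl.sigma > 0:
            site_log10 = site_log10 + rng.normal(0.0, cpl.sigma, config.n_sites)
        for si, site in enumerate(truth.site_ids):
            for ri in range(config.n_replicates):
                lg = site_log10[si]
                if truth.gene_replicate_sigma > 0:
                    lg = lg + rng.normal(0.0, truth.gene_replicate_sigma)
                rows.append(
                    {"site_id": site, "replicate_id": f"rep{ri + 1}",
                     "gene": gene, "copies": float(10.0 ** lg)}
                )
    return pd.DataFrame(rows, columns=["site_id", "replicate_id", "gene", "copies"])


def simulate_environment(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Site covariate table with precipitation loosely tracking activity.

    Wetter sites tend to be more active, so MAP is coupled to the site's log
    total activity; the remaining covariates are drawn in field-plausible
    ranges for temperate and alpine grassland soils.
    """
    rng = _rng(truth.seed, 404)
    assay = config.assays[0]
    totals = sum(truth.rates[assay][g] for g in GUILDS)
    z = np.log(np.maximum(totals, 1e-6))
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    n = config.n_sites
    return pd.DataFrame(
        {
            "site_id": truth.site_ids,
            "MAP": np.round(320.0 + 110.0 * z + rng.normal(0, 35, n), 1),
            "MAT": np.round(rng.uniform(-2.0, 8.0, n), 2),
            "pH": np.round(np.clip(rng.normal(7.6, 0.7, n), 4.5, 9.5), 2),
            "SM": np.round(np.clip(12.0 + 6.0 * z + rng.normal(0, 3, n), 0.5, 60.0), 2),
            "TC": np.round(np.clip(22.0 + 8.0 * z + rng.normal(0, 4, n), 2.0, 80.0), 2),
            "TN": np.round(np.clip(2.2 + 0.8 * z + rng.normal(0, 0.4, n), 0.2, 8.0), 3),
            "NH4_N": np.round(np.clip(rng.normal(5.5, 1.5, n), 0.2, 20.0), 3),
            "NO3_N": np.round(np.clip(rng.normal(8.0, 2.5, n), 0.2, 40.0), 3),
        }
    )


def generate_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic file set and the truth sidecar.

    Emits measurements.csv, genes.csv, environment.csv and truth.json in the
    pipeline's input dialects; returns the paths. truth.json is a sidecar for
    validation only — no analysis stage reads it.
    """
    from .io import write_measurements  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = draw_truth(config)
    paths = {
        "measurements": outdir / "measurements.csv",
        "genes": outdir / "genes.csv",
        "environment": outdir / "environment.csv",
        "truth": outdir / "truth.json",
    }
    write_measurements(simulate_measurements(truth, config), paths["measurements"])
    simulate_genes(truth, config).to_csv(paths["genes"], index=False)
    simulate_environment(truth, config).to_csv(paths["environment"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
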