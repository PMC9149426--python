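"""Guild partitioning of potential enzyme activities by inhibitor differences.

The selective-inhibition design runs parallel incubations of the same soil
under a no-inhibitor control (A), a bactericide (streptomycin, B), a fungicide
(cycloheximide, C), both inhibitors combined (D), an autoclave-sterilized
treatment, and optionally an archaeal inhibitor (simvastatin). With the fitted
slopes k of each treatment the bulk activity splits as

    total     = k_control
    bacterial = total − k_bactericide
    fungal    = total − k_fungicide
    archaeal  = total − bacterial − fungal − k_sterilized
    abiotic   = k_sterilized

so that bacterial + fungal + archaeal + abiotic == total is an exact algebraic
identity on the raw (unclamped) components. The inhibitor additivity ratio

    IAR = [(A − B) + (A − C)] / (A − D)

checks that the two inhibitors act specifically and additively (IAR ≈ 1);
off-target suppression pushes it away from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    IncompleteDesignError,
    InsufficientPairsError,
    InvalidInputError,
    NoSignalError,
    UndefinedRatioError,
)

GUILDS = ("bacterial", "fungal", "archaeal", "abiotic")

#: Smallest reported total denitrification activity; the default floor below
#: which a site's per-site contribution ratio is considered unreliable.
DEFAULT_TOTAL_FLOOR = 0.05

DEFAULT_IAR_BAND = (0.9, 1.1)


@dataclass(frozen=True)
class TreatmentSlopes:
    """Per-treatment slope summary for one site × assay.

    ``replicates`` optionally retains the replicate-level slopes behind each
    summary mean; bottles are independent across treatments (no pairing).
    """

    site_id: str
    assay: str
    k_control: float
    k_bactericide: float
    k_fungicide: float
    k_sterilized: float
    k_combined: float | None = None
    k_archaeal_inhibitor: float | None = None
    replicates: Mapping[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.replicates is not None:
            reps = {t: tuple(float(v) for v in vs) for t, vs in self.replicates.items()}
            if any(len(v) == 0 for v in reps.values()):
                raise InvalidInputError(f"{self.site_id}/{self.assay}: empty replicate list")
            object.__setattr__(self, "replicates", reps)


@dataclass(frozen=True)
class GuildPartition:
    """Raw and clamped guild components for one site × assay."""

    site_id: str
    assay: str
    total: float
    raw: Mapping[str, float]
    clamped: Mapping[str, float]
    clamp_flags: Mapping[str, bool]
    sem: Mapping[str, float] | None = None


@dataclass(frozen=True)
class IarRecord:
    site_id: str
    assay: str
    a: float
    b: float
    c: float
    d: float
    iar: float
    band: tuple[float, float]
    passed: bool


@dataclass(frozen=True)
class ContributionSummary:
    assay: str
    mode: str
    percentages: Mapping[str, float]
    ci: Mapping[str, tuple[float, float]]
    n_sites: int
    excluded_sites: tuple[str, ...]
    n_boot: int
    seed: int | None


@dataclass(frozen=True)
class ArchaealVerification:
    """Difference-method vs simvastatin-method archaeal activity comparison."""

    site_ids: tuple[str, ...]
    method1: tuple[float, ...]
    method2: tuple[float, ...]
    test: str
    statistic: float
    p_value: float
    methods_agree: bool


def partition_activity(slopes: TreatmentSlopes, clamp: bool = True) -> GuildPartition:
    """Apply the inhibitor-difference algebra to one site × assay.

    Negative raw components (sampling noise, slight over-inhibition) are
    clamped to 0 for reporting when ``clamp`` is on; raw values and flags are
    always retained so the diagnostics survive.
    """
    for name in ("k_control", "k_bactericide", "k_fungicide", "k_sterilized"):
        if getattr(slopes, name) is None:
            raise IncompleteDesignError(f"{slopes.site_id}/{slopes.assay}: missing {name}")
    total = slopes.k_control
    bacterial = total - slopes.k_bactericide
    fungal = total - slopes.k_fungicide
    abiotic = slopes.k_sterilized
    archaeal = total - bacterial - fungal - abiotic
    raw = {"bacterial": bacterial, "fungal": fungal, "archaeal": archaeal, "abiotic": abiotic}
    if clamp:
        clamped = {g: max(v, 0.0) for g, v in raw.items()}
        flags = {g: v < 0.0 for g, v in raw.items()}
    else:
        clamped = dict(raw)
        flags = {g: False for g in raw}
    return GuildPartition(slopes.site_id, slopes.assay, total, raw, clamped, flags)


def compute_iar(
    slopes: TreatmentSlopes, band: tuple[float, float] = DEFAULT_IAR_BAND
) -> IarRecord:
    """Inhibitor additivity ratio for one site × assay.

    Requires the combined (bactericide + fungicide) treatment. The ratio is
    undefined when control equals combined — no biotic signal was removed, so
    additivity cannot be assessed.
    """
    if slopes.k_combined is None:
        raise IncompleteDesignError(f"{slopes.site_id}/{slopes.assay}: no combined treatment")
    a, b, c, d = slopes.k_control, slopes.k_bactericide, slopes.k_fungicide, slopes.k_combined
    if a == d:
        raise UndefinedRatioError(
            f"{slopes.site_id}/{slopes.assay}: control equals combined slope; IAR undefined"
        )
    iar = ((a - b) + (a - c)) / (a - d)
    return IarRecord(slopes.site_id, slopes.assay, a, b, c, d, iar, band, band[0] <= iar <= band[1])


def summarize_contributions(
    partitions: Sequence[GuildPartition],
    mode: str = "pooled",
    n_boot: int = 1000,
    seed: int | None = None,
    floor: float = DEFAULT_TOTAL_FLOOR,
) -> ContributionSummary:
    """Transect-level guild contribution percentages with bootstrap CIs.

    pooled:        guild% = Σ_sites guild / Σ_sites total × 100. Robust to
                   near-zero totals at individual sites.
    per_site_mean: mean over sites of per-site guild/total × 100; sites whose
                   total falls below ``floor`` are excluded and reported,
                   because the ratio is unstable there.

    CIs are percentile intervals from resampling sites with replacement.
    Clamped component values are used throughout.
    """
    if not partitions:
        raise InvalidInputError("no partitions to summarize")
    assays = {p.assay for p in partitions}
    if len(assays) > 1:
        raise InvalidInputError(f"mixed assays in one summary: {sorted(assays)}")
    if mode not in ("pooled", "per_site_mean"):
        raise InvalidInputError(f"unknown aggregation mode {mode!r}")

    comp = np.array([[p.clamped[g] for g in GUILDS] for p in partitions])  # sites × guilds
    totals = np.array([p.total for p in partitions])
    site_ids = [p.site_id for p in partitions]

    if mode == "per_site_mean":
        keep = totals >= floor
        excluded = tuple(s for s, k in zip(site_ids, keep) if not k)
        if not keep.any():
            raise NoSignalError(f"all totals below floor {floor}")
        comp, totals = comp[keep], totals[keep]
    else:
        excluded = ()
        if totals.sum() <= 0:
            raise NoSignalError("pooled total activity is zero")

    def shares(c: np.ndarray, t: np.ndarray) -> np.ndarray:
        if mode == "pooled":
            return c.sum(axis=0) / t.sum() * 100.0
        return (c / t[:, None] * 100.0).mean(axis=0)

    point = shares(comp, totals)
    n = len(totals)
    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0 and n > 1:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, len(GUILDS)))
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            draws[i] = shares(comp[idx], totals[idx])
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        ci = {g: (float(l), float(h)) for g, l, h in zip(GUILDS, lo, hi)}
    else:
        ci = {g: (float(v), float(v)) for g, v in zip(GUILDS, point)}

    return ContributionSummary(
        assay=partitions[0].assay,
        mode=mode,
        percentages={g: float(v) for g, v in zip(GUILDS, point)},
        ci=ci,
        n_sites=n,
        excluded_sites=excluded,
        n_boot=n_boot,
        seed=seed,
    )


def verify_archaeal_methods(
    slopes_list: Sequence[TreatmentSlopes], test: str = "wilcoxon"
) -> ArchaealVerification:
    """Cross-validate the archaeal estimate against the simvastatin method.

    method 1 (difference): archaeal component from the four-treatment algebra.
    method 2 (specific inhibitor): k_control − k_archaeal_inhibitor.

    A paired test on (method1 − method2) with p > 0.05 means the two methods
    are statistically indistinguishable, supporting the difference design.
    Raw (unclamped) archaeal components are compared.
    """
    if test not in ("wilcoxon", "paired_t"):
        raise InvalidInputError(f"unknown test {test!r}")
    pairs = []
    for s in slopes_list:
        if s.k_archaeal_inhibitor is None:
            raise IncompleteDesignError(f"{s.site_id}/{s.assay}: no archaeal-inhibitor slope")
        m1 = partition_activity(s, clamp=False).raw["archaeal"]
        m2 = s.k_control - s.k_archaeal_inhibitor
        pairs.append((s.site_id, m1, m2))
    if len(pairs) < 3:
        raise InsufficientPairsError(f"need >=3 paired sites, got {len(pairs)}")
    ids, m1, m2 = zip(*pairs)
    diffs = np.asarray(m1) - np.asarray(m2)
    if np.all(diffs == 0.0):
        stat, p = 0.0, 1.0
    elif test == "wilcoxon":
        stat, p = stats.wilcoxon(diffs)
    else:
        stat, p = stats.ttest_rel(m1, m2)
    return ArchaealVerification(
        site_ids=tuple(ids),
        method1=tuple(float(v) for v in m1),
        method2=tuple(float(v) for v in m2),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        methods_agree=bool(p > 0.05),
    )


def propagate_uncertainty(
    replicate_slopes: Mapping[str, Sequence[float]],
    n_boot: int = 1000,
    seed: int | None = None,
    clamp: bool = True,
    site_id: str = "",
    assay: str = "nitrification",
) -> dict[str, float | None]:
    """Bootstrap SEM of each guild component from replicate-level slopes.

    Bottles are independent across treatments, so replicates are resampled
    independently within each treatment, the partition recomputed per draw,
    and the SEM taken as the standard deviation of the bootstrap component
    estimates. Treatments with <2 replicates make the SEM unidentifiable:
    every component is reported missing (None) rather than as a false zero.
    """
    required = ("control", "bactericide", "fungicide", "sterilized")
    for t in required:
        if t not in replicate_slopes:
            raise IncompleteDesignError(f"missing replicate slopes for {t}")
    reps = {t: np.asarray(replicate_slopes[t], dtype=float) for t in required}
    if any(len(v) < 2 for v in reps.values()):
        return {g: None for g in GUILDS} | {"total": None}
    rng = np.random.default_rng(seed)
    comps = np.empty((n_boot, len(GUILDS) + 1))
    for i in range(n_boot):
        means = {
            t: float(rng.choice(v, size=len(v), replace=True).mean()) for t, v in reps.items()
        }
        p = partition_activity(
            TreatmentSlopes(
                site_id,
                assay,
                means["control"],
                means["bactericide"],
                means["fungicide"],
                means["sterilized"],
            ),
            clamp=clamp,
        )
        comps[i] = [p.clamped[g] for g in GUILDS] + [p.total]
    sd = comps.std(axis=0, ddof=1)
    out: dict[str, float | None] = {g: float(s) for g, s in zip(GUILDS, sd)}
    out["total"] = float(sd[-1])
    return out
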