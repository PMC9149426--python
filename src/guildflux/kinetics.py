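"""Incubation kinetics: unit conversions and linear production-rate estimation.

A potential-activity assay incubates a soil slurry (or sealed bottle with an
acetylene-amended headspace) under substrate excess and measures the product
pool — NO2- + NO3- for nitrification, N2O for denitrification — at a few time
points. Under substrate excess the accumulation is linear, and the enzyme
activity is the slope ``k`` of product amount (μg N per g dry soil) against
time (h). This module converts raw analyser readings to per-gram amounts and
fits ``k`` by ordinary least squares with linearity diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InvalidInputError

ASSAYS = ("nitrification", "denitrification")
TREATMENTS = (
    "control",
    "bactericide",
    "fungicide",
    "combined",
    "sterilized",
    "archaeal_inhibitor",
)

#: Ideal gas constant in L·atm·K⁻¹·mol⁻¹.
R_L_ATM = 0.0820573660809596
#: Grams of N per mole of N2O (two N atoms).
G_N_PER_MOL_N2O = 28.0134
#: Default incubation temperature (28 °C) in kelvin.
DEFAULT_TEMPERATURE_K = 301.15


@dataclass(frozen=True)
class IncubationSeries:
    """One bottle's product time course under one treatment.

    Amounts are expressed per gram of dry soil so that bottles with slightly
    different soil masses are directly comparable.
    """

    site_id: str
    replicate_id: str
    assay: str
    treatment: str
    times: tuple[float, ...]
    amounts: tuple[float, ...]
    dry_soil_mass: float = 10.0
    slurry_volume: float = 80.0
    headspace_volume: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise InvalidInputError(f"unknown assay {self.assay!r}")
        if self.treatment not in TREATMENTS:
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")
        times = tuple(float(t) for t in self.times)
        amounts = tuple(float(a) for a in self.amounts)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amounts", amounts)
        if len(times) < 3:
            raise InvalidInputError(
                f"{self.label}: need >=3 sampling times, got {len(times)}"
            )
        if len(amounts) != len(times):
            raise InvalidInputError(f"{self.label}: times/amounts length mismatch")
        if times[0] != 0.0:
            raise InvalidInputError(f"{self.label}: first sampling time must be 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError(f"{self.label}: times must be strictly increasing")
        if any(a < 0 for a in amounts):
            raise InvalidInputError(
                f"{self.label}: negative amounts are rejected; encode blanks as missing"
            )
        if self.dry_soil_mass <= 0:
            raise InvalidInputError(f"{self.label}: dry_soil_mass must be > 0")

    @property
    def label(self) -> str:
        return f"{self.site_id}/{self.replicate_id}/{self.assay}/{self.treatment}"


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of product amount vs time with fit diagnostics.

    ``r_squared`` is ``None`` (reported missing) when the response has zero
    variance: a perfectly flat blank has no meaningful coefficient of
    determination.
    """

    k: float
    intercept: float
    se_k: float
    r_squared: float | None
    n_points: int
    label: str = ""


def convert_slurry_concentration(
    conc: float,
    slurry_volume: float,
    dry_soil_mass: float,
    correct_removal: bool = False,
    removals: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Convert a filtrate N concentration to μg N per g dry soil.

    Parameters
    ----------
    conc:
        Measured concentration, mg N per L of filtrate (== μg N per ml).
    slurry_volume:
        Current slurry volume in ml (after any prior withdrawals).
    dry_soil_mass:
        Dry-soil equivalent in the bottle, g.
    correct_removal:
        When True, N mass withdrawn at earlier samplings is added back so the
        amount reflects cumulative production rather than the standing pool.
    removals:
        Prior withdrawals as ``(volume_ml, conc_mgN_L)`` pairs; only allowed
        (and required) when ``correct_removal`` is on.
    """
    if slurry_volume <= 0 or dry_soil_mass <= 0:
        raise InvalidInputError("slurry_volume and dry_soil_mass must be > 0")
    if conc < 0:
        raise InvalidInputError("concentration must be >= 0")
    if removals and not correct_removal:
        raise InvalidInputError("removals given but correct_removal is off")
    mass_ug = conc * slurry_volume  # mg/L == μg/ml
    if correct_removal:
        for vol, c in removals or ():
            if vol <= 0 or c < 0:
                raise InvalidInputError("removal volumes must be > 0, concs >= 0")
            mass_ug += c * vol
    return mass_ug / dry_soil_mass


def convert_headspace_n2o(
    mixing_ratio: float,
    headspace_volume: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    pressure: float = 1.0,
    dry_soil_mass: float = 10.0,
) -> float:
    """Convert a headspace N2O mixing ratio (ppm) to μg N2O-N per g dry soil.

    Ideal-gas moles ``n = x·1e-6 · P·V / (R·T)`` times 28 g N per mol N2O.
    Dissolved N2O in the slurry is deliberately ignored: with the acetylene
    block and a shaken bottle, the headspace holds the large majority of the
    N2O and the dissolved fraction cancels out of slope comparisons.
    """
    if mixing_ratio < 0:
        raise InvalidInputError("mixing ratio must be >= 0")
    if temperature <= 0 or headspace_volume <= 0 or pressure <= 0 or dry_soil_mass <= 0:
        raise InvalidInputError("temperature, volumes, pressure and mass must be > 0")
    moles = mixing_ratio * 1e-6 * pressure * (headspace_volume / 1000.0) / (R_L_ATM * temperature)
    return moles * G_N_PER_MOL_N2O * 1e6 / dry_soil_mass


def fit_rate(series: IncubationSeries) -> RateEstimate:
    """Estimate the linear production rate ``k`` for one bottle by OLS.

    Returns slope, intercept, the slope's standard error and r² from the same
    two-parameter fit. With only two points the fit is exact and ``se_k`` is 0.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.amounts, dtype=float)
    if len(np.unique(t)) < 2:
        raise DegenerateDesignError(f"{series.label}: <2 distinct time points")
    if np.ptp(y) == 0.0:
        # Flat response: slope is exactly 0 and r² is undefined (0/0).
        return RateEstimate(0.0, float(y[0]), 0.0, None, len(t), series.label)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    se = float(res.stderr) if math.isfinite(res.stderr) else 0.0
    return RateEstimate(float(res.slope), float(res.intercept), se, r2, len(t), series.label)


@dataclass(frozen=True)
class LinearityCheck:
    passed: bool
    message: str


def qc_linearity(estimate: RateEstimate, min_r2: float = 0.9) -> LinearityCheck:
    """Flag fits whose r² falls below ``min_r2``.

    A missing r² passes only for a flat blank (k == 0): a constant response
    carries no evidence against linearity, whereas a sloped fit must justify
    itself. The estimate is never mutated.
    """
    if estimate.r_squared is None:
        if estimate.k == 0.0:
            return LinearityCheck(True, f"{estimate.label}: flat response, r2 undefined")
        return LinearityCheck(False, f"{estimate.label}: r2 undefined with nonzero slope")
    if estimate.r_squared >= min_r2:
        return LinearityCheck(True, f"{estimate.label}: r2={estimate.r_squared:.3f}")
    return LinearityCheck(
        False,
        f"{estimate.label}: r2={estimate.r_squared:.3f} below threshold {min_r2:.3f}",
    )
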