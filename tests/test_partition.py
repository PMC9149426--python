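"""Inhibitor-difference algebra, IAR, contributions and uncertainty."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildflux import (
    TreatmentSlopes,
    compute_iar,
    partition_activity,
    propagate_uncertainty,
    summarize_contributions,
    verify_archaeal_methods,
)
from guildflux.errors import (
    IncompleteDesignError,
    InsufficientPairsError,
    NoSignalError,
    UndefinedRatioError,
)
from guildflux.partition import GUILDS


def slopes(control, bact, fung, ster, combined=None, arch=None, site="s1",
           assay="nitrification", replicates=None):
    return TreatmentSlopes(site, assay, control, bact, fung, ster,
                           k_combined=combined, k_archaeal_inhibitor=arch,
                           replicates=replicates)


class TestPartition:
    def test_stated_algebra(self):
        p = partition_activity(slopes(1.0, 0.7, 0.6, 0.1))
        assert p.total == pytest.approx(1.0)
        assert p.raw["bacterial"] == pytest.approx(0.3)
        assert p.raw["fungal"] == pytest.approx(0.4)
        assert p.raw["archaeal"] == pytest.approx(0.2)
        assert p.raw["abiotic"] == pytest.approx(0.1)

    def test_equal_slopes_all_abiotic(self):
        p = partition_activity(slopes(0.5, 0.5, 0.5, 0.5))
        assert p.raw["bacterial"] == p.raw["fungal"] == p.raw["archaeal"] == 0.0
        assert p.raw["abiotic"] == 0.5

    def test_negative_archaeal_clamped_with_flag(self):
        p = partition_activity(slopes(1.0, 0.5, 0.5, 0.2))
        assert p.raw["archaeal"] == pytest.approx(-0.2)
        assert p.clamped["archaeal"] == 0.0
        assert p.clamp_flags["archaeal"]
        assert not p.clamp_flags["bacterial"]

    def test_missing_slope_errors(self):
        with pytest.raises(IncompleteDesignError):
            partition_activity(slopes(1.0, 0.7, 0.6, None))

    @given(
        k=st.tuples(*[st.floats(-5, 5, allow_nan=False) for _ in range(4)]),
    )
    @settings(max_examples=300, deadline=None)
    def test_conservation_identity(self, k):
        p = partition_activity(slopes(*k), clamp=True)
        assert abs(sum(p.raw[g] for g in GUILDS) - p.total) <= 1e-12

    @given(delta=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_bactericide_monotonicity(self, delta):
        base = partition_activity(slopes(2.0, 1.0, 1.2, 0.1))
        moved = partition_activity(slopes(2.0, 1.0 + delta, 1.2, 0.1))
        assert moved.raw["bacterial"] == pytest.approx(base.raw["bacterial"] - delta)


class TestIar:
    def test_perfect_additivity(self):
        assert compute_iar(slopes(1.0, 0.7, 0.6, 0.1, combined=0.3)).iar == pytest.approx(1.0)

    def test_no_inhibition(self):
        assert compute_iar(slopes(1.0, 1.0, 1.0, 0.1, combined=0.3)).iar == pytest.approx(0.0)

    def test_direct_formula(self):
        r = compute_iar(slopes(1.0, 0.6, 0.5, 0.1, combined=0.3))
        assert r.iar == pytest.approx(0.9 / 0.7, rel=1e-12)
        assert not r.passed  # 1.2857 outside [0.9, 1.1]

    @given(c=st.floats(0.01, 100), seed=st.integers(0, 999))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(1, 2)
        b, f, d = a * rng.uniform(0.2, 0.9, 3)
        base = compute_iar(slopes(a, b, f, 0.0, combined=d)).iar
        scaled = compute_iar(slopes(a * c, b * c, f * c, 0.0, combined=d * c)).iar
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_undefined_when_control_equals_combined(self):
        with pytest.raises(UndefinedRatioError):
            compute_iar(slopes(1.0, 0.7, 0.6, 0.1, combined=1.0))


def make_partition(total, bact, fung, arch, abio, site="s1"):
    return partition_activity(
        slopes(total, total - bact, total - fung, abio, site=site)
    )


class TestContributions:
    def test_single_partition_percentages(self):
        s = summarize_contributions([make_partition(1.0, 0.3, 0.4, 0.2, 0.1)], n_boot=0)
        assert s.percentages == pytest.approx(
            {"bacterial": 30.0, "fungal": 40.0, "archaeal": 20.0, "abiotic": 10.0}
        )

    def test_duplication_idempotence(self):
        parts = [make_partition(1.0, 0.3, 0.4, 0.2, 0.1, site=f"s{i}") for i in (1, 2)]
        one = summarize_contributions(parts[:1], n_boot=0)
        two = summarize_contributions(parts, n_boot=0)
        assert two.percentages == pytest.approx(one.percentages)

    def test_pooled_vs_per_site_mean_hand_oracle(self):
        # totals (1.0, 2.0), fungal (0.4, 1.4):
        # pooled 1.8/3.0 = 60%; per-site mean (40% + 70%)/2 = 55%.
        parts = [
            make_partition(1.0, 0.3, 0.4, 0.2, 0.1, site="s1"),
            make_partition(2.0, 0.2, 1.4, 0.3, 0.1, site="s2"),
        ]
        pooled = summarize_contributions(parts, mode="pooled", n_boot=0)
        per_site = summarize_contributions(parts, mode="per_site_mean", n_boot=0)
        assert pooled.percentages["fungal"] == pytest.approx(60.0)
        assert per_site.percentages["fungal"] == pytest.approx(55.0)

    def test_floor_excludes_low_total_sites(self):
        parts = [
            make_partition(1.0, 0.3, 0.4, 0.2, 0.1, site="hot"),
            make_partition(0.01, 0.004, 0.003, 0.002, 0.001, site="cold"),
        ]
        s = summarize_contributions(parts, mode="per_site_mean", n_boot=0, floor=0.05)
        assert s.excluded_sites == ("cold",)
        assert s.n_sites == 1

    def test_all_below_floor_errors(self):
        parts = [make_partition(0.01, 0.004, 0.003, 0.002, 0.001)]
        with pytest.raises(NoSignalError):
            summarize_contributions(parts, mode="per_site_mean", floor=0.05)

    def test_bootstrap_ci_deterministic_given_seed(self):
        parts = [
            make_partition(1.0, 0.3, 0.4, 0.2, 0.1, site=f"s{i}")
            for i in range(4)
        ]
        a = summarize_contributions(parts, n_boot=200, seed=5)
        b = summarize_contributions(parts, n_boot=200, seed=5)
        assert a.ci == b.ci


def wilcoxon_oracle(diffs):
    """Exact signed-rank two-sided p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_min_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_min_obs:
            count += 1
    return count / 2**n


class TestArchaealVerification:
    def _slopes(self, site, control, arch_true, assay="denitrification"):
        # Perfect specificity: simvastatin slope = control - archaeal rate.
        return slopes(control, control - 0.2, control - 0.3, 0.05,
                      arch=control - arch_true, site=site, assay=assay)

    def test_identical_methods_agree(self):
        # Binary-exact slope values so method1 - method2 is exactly zero.
        designs = [
            # (control, bactericide, fungicide, sterilized, archaeal_rate)
            (1.0, 0.75, 0.5, 0.0, 0.25),
            (2.0, 1.5, 1.0, 0.25, 0.25),
            (0.5, 0.375, 0.25, 0.0625, 0.0625),
        ]
        records = []
        for i, (a, b, f, s, arch) in enumerate(designs):
            records.append(slopes(a, b, f, s, arch=a - arch, site=f"s{i}"))
        v = verify_archaeal_methods(records)
        assert v.method1 == v.method2
        assert v.p_value == 1.0
        assert v.methods_agree

    def test_wilcoxon_against_enumeration_oracle(self):
        # Tie-free differences: method1 - method2 = (0.2, 0.3, -0.1, 0.45).
        diffs = [0.2, 0.3, -0.1, 0.45]
        records = []
        for i, d in enumerate(diffs):
            # archaeal raw = 1.0 - 0.3 - 0.2 - 0.1 = 0.4; method2 = 0.4 - d.
            records.append(
                slopes(1.0, 0.7, 0.8, 0.1, arch=1.0 - (0.4 - d), site=f"s{i}")
            )
        v = verify_archaeal_methods(records, test="wilcoxon")
        assert np.asarray(v.method1) - np.asarray(v.method2) == pytest.approx(diffs)
        assert v.p_value == pytest.approx(wilcoxon_oracle(diffs), abs=1e-12)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientPairsError):
            verify_archaeal_methods([self._slopes("s1", 1.0, 0.2)])


class TestUncertainty:
    REPS = {
        "control": (1.0, 1.1),
        "bactericide": (0.7, 0.75),
        "fungicide": (0.6, 0.62),
        "sterilized": (0.1, 0.12),
    }

    def test_zero_variance_gives_zero_sem(self):
        reps = {t: (v[0], v[0]) for t, v in self.REPS.items()}
        sem = propagate_uncertainty(reps, n_boot=100, seed=1)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in sem.values())

    def test_deterministic_given_seed(self):
        a = propagate_uncertainty(self.REPS, n_boot=300, seed=9)
        b = propagate_uncertainty(self.REPS, n_boot=300, seed=9)
        assert a == b

    def test_single_replicate_reports_missing(self):
        reps = dict(self.REPS, control=(1.0,))
        sem = propagate_uncertainty(reps, n_boot=100, seed=1)
        assert all(v is None for v in sem.values())

    def test_bootstrap_matches_exhaustive_enumeration(self):
        # Two replicates per treatment: each bootstrap treatment mean is a, b
        # or (a+b)/2 with weights 1/4, 1/4, 1/2; enumerate all 3^4 = 81
        # combinations exactly and compare the bacterial-component SD.
        reps = self.REPS
        options = {
            t: [(v[0], 0.25), (v[1], 0.25), ((v[0] + v[1]) / 2, 0.5)]
            for t, v in reps.items()
        }
        vals, weights = [], []
        for combo in itertools.product(*(options[t] for t in
                                         ("control", "bactericide", "fungicide", "sterilized"))):
            (c, wc), (b, wb), (f, wf), (s, ws) = combo
            vals.append(c - b)  # bacterial component, no clamping needed (all > 0)
            weights.append(wc * wb * wf * ws)
        vals, weights = np.array(vals), np.array(weights)
        mean = (vals * weights).sum()
        exact_sd = np.sqrt(((vals - mean) ** 2 * weights).sum())
        sem = propagate_uncertainty(reps, n_boot=8000, seed=3, clamp=False)
        assert sem["bacterial"] == pytest.approx(exact_sd, rel=0.10)
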