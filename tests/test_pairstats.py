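"""Matched-sampling relative risk, empirical p-values, directionality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from trajmine.cohort import Cohort, assign_age_groups
from trajmine.pairstats import (
    BOTH_DROPPED,
    FORWARD,
    REVERSE,
    PairStats,
    SamplingConfig,
    adjust_pvalues,
    compute_pair_stats,
    directionality_test,
    estimate_rr,
    pair_occurs,
    pair_rng,
    prefilter_pairs,
    sample_comparison_group,
    select_pairs,
)
from conftest import make_cohort, make_patient, random_cohort

WINDOW = dict(min_gap=183, max_gap=1825)


class TestPairOccurs:
    @pytest.mark.parametrize(
        "day_b,expected",
        [(731, True), (31, False), (183, True), (1825, True), (1826, False)],
    )
    def test_window_is_inclusive(self, day_b, expected):
        p = make_patient("x", [("A", 0), ("B", day_b)])
        assert pair_occurs(p, "A", "B", **WINDOW) is expected

    def test_missing_code(self):
        p = make_patient("x", [("A", 0)])
        assert pair_occurs(p, "A", "B", **WINDOW) is False


class TestPrefilter:
    def test_threshold_excludes_rare_pairs(self):
        cohort = make_cohort([(f"p{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(3)])
        cfg = SamplingConfig(min_patients=100, **WINDOW)
        assert prefilter_pairs(cohort, cfg) == []

    def test_min_one_keeps_any_supported_pair(self):
        cohort = make_cohort([("p0", 1, 1950, [("A", 0), ("B", 400)])])
        cfg = SamplingConfig(min_patients=1, **WINDOW)
        assert ("A", "B") in prefilter_pairs(cohort, cfg)
        assert ("B", "A") not in prefilter_pairs(cohort, cfg)

    def test_counts_match_brute_force(self):
        from oracles import windowed_pair_count

        rng = np.random.default_rng(42)
        cohort = random_cohort(rng, n_patients=50)
        cfg = SamplingConfig(min_patients=3, **WINDOW)
        got = set(prefilter_pairs(cohort, cfg))
        codes = cohort.codes
        expected = {
            (a, b)
            for a in codes
            for b in codes
            if a != b and windowed_pair_count(cohort, a, b, 183, 1825) >= 3
        }
        assert got == expected


class TestComparisonSampling:
    def _cohort(self, n_exposed, n_unexposed):
        specs = [(f"e{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(n_exposed)]
        specs += [(f"u{i}", 1, 1950, [("B", 300)]) for i in range(n_unexposed)]
        return make_cohort(specs, n_age_groups=1)

    def test_draws_match_exposed_count_per_stratum(self):
        cohort = self._cohort(10, 50)
        exposed = ~np.isnan(cohort.days_of("A"))
        e, c, shortfall = sample_comparison_group(cohort, exposed, np.random.default_rng(0))
        assert len(e) == len(c) == 10
        assert shortfall == 0
        assert not exposed[c].any()

    def test_shortfall_truncates_both_groups(self):
        cohort = self._cohort(10, 4)
        exposed = ~np.isnan(cohort.days_of("A"))
        e, c, shortfall = sample_comparison_group(cohort, exposed, np.random.default_rng(0))
        assert len(e) == len(c) == 4
        assert shortfall == 6

    def test_identical_seed_identical_sample(self):
        cohort = self._cohort(10, 50)
        exposed = ~np.isnan(cohort.days_of("A"))
        a = sample_comparison_group(cohort, exposed, np.random.default_rng(7))
        b = sample_comparison_group(cohort, exposed, np.random.default_rng(7))
        assert (a[1] == b[1]).all()


def exhaustive_fixture(n_exposed=100, n_unexposed=100, n_ab=30, n_b_unexposed=10):
    """Two clean arms: exposed with/without B after A, unexposed with/without B."""
    specs = []
    for i in range(n_exposed):
        evs = [("A", 0)] + ([("B", 400)] if i < n_ab else [])
        specs.append((f"e{i}", 1, 1950, evs))
    for i in range(n_unexposed):
        evs = [("B", 200)] if i < n_b_unexposed else [("C", 100)]
        specs.append((f"u{i}", 1, 1950, evs))
    return make_cohort(specs, n_age_groups=1)


class TestEstimateRR:
    def test_exhaustive_mode_two_cohort_rr(self):
        cohort = exhaustive_fixture()
        cfg = SamplingConfig(iterations=1, exhaustive=True, min_patients=1, **WINDOW)
        s = estimate_rr(cohort, "A", "B", cfg)
        assert s.rr == pytest.approx(3.0)
        assert s.n_ab == 30

    def test_equal_rates_give_unit_rr(self):
        cohort = exhaustive_fixture(n_ab=20, n_b_unexposed=20)
        cfg = SamplingConfig(iterations=1, exhaustive=True, min_patients=1, **WINDOW)
        assert estimate_rr(cohort, "A", "B", cfg).rr == pytest.approx(1.0)

    def test_sampled_rr_close_to_stratified_oracle(self):
        from oracles import stratified_expected_rr

        rng = np.random.default_rng(5)
        cohort = random_cohort(rng, n_patients=200, codes=("A", "B", "C"), p_code=0.6)
        cfg = SamplingConfig(iterations=2000, min_patients=1, rng_seed=3, **WINDOW)
        for a, b in (("A", "B"), ("B", "C")):
            s = estimate_rr(cohort, a, b, cfg)
            oracle = stratified_expected_rr(cohort, a, b, 183, 1825)
            assert s.rr == pytest.approx(oracle, rel=0.05)

    def test_all_patients_exposed_is_unsampleable(self):
        cohort = make_cohort([(f"p{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(5)])
        cfg = SamplingConfig(iterations=10, min_patients=1, **WINDOW)
        assert estimate_rr(cohort, "A", "B", cfg).unsampleable

    def test_zero_comparison_rate_gives_infinite_rr(self):
        specs = [(f"e{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(5)]
        specs += [(f"u{i}", 1, 1950, [("C", 100)]) for i in range(5)]
        cohort = make_cohort(specs, n_age_groups=1)
        cfg = SamplingConfig(iterations=10, min_patients=1, **WINDOW)
        s = estimate_rr(cohort, "A", "B", cfg)
        assert math.isinf(s.rr)
        assert s.p_value == pytest.approx(1 / 11)

    def test_identical_seed_bit_identical_stats(self):
        rng = np.random.default_rng(9)
        cohort = random_cohort(rng, n_patients=80)
        cfg = SamplingConfig(iterations=50, min_patients=1, rng_seed=11, **WINDOW)
        s1 = compute_pair_stats(cohort, cfg)
        s2 = compute_pair_stats(cohort, cfg)
        assert {k: (v.rr, v.p_value) for k, v in s1.items()} == {
            k: (v.rr, v.p_value) for k, v in s2.items()
        }

    def test_result_independent_of_pair_order(self):
        rng = np.random.default_rng(10)
        cohort = random_cohort(rng, n_patients=80)
        cfg = SamplingConfig(iterations=50, min_patients=1, rng_seed=11, **WINDOW)
        pairs = prefilter_pairs(cohort, cfg)
        fwd = compute_pair_stats(cohort, cfg, pairs=pairs)
        rev = compute_pair_stats(cohort, cfg, pairs=pairs[::-1])
        for k in fwd:
            assert fwd[k].rr == rev[k].rr and fwd[k].p_value == rev[k].p_value

    def test_p_value_bounds(self):
        rng = np.random.default_rng(12)
        cohort = random_cohort(rng, n_patients=60)
        cfg = SamplingConfig(iterations=40, min_patients=1, rng_seed=0, **WINDOW)
        for s in compute_pair_stats(cohort, cfg).values():
            if not s.unsampleable:
                assert 1 / 41 <= s.p_value <= 1.0


class TestDirectionality:
    @pytest.mark.parametrize(
        "f,r,p,direction",
        [
            (10, 0, 0.001953125, FORWARD),
            (7, 3, 0.34375, BOTH_DROPPED),
            (5, 5, 1.0, BOTH_DROPPED),
            (0, 10, 0.001953125, REVERSE),
            (0, 0, 1.0, BOTH_DROPPED),
        ],
    )
    def test_worked_examples(self, f, r, p, direction):
        d, pv = directionality_test(f, r, alpha=0.05)
        assert pv == pytest.approx(p, abs=1e-15)
        assert d == direction

    @given(n=st.integers(1, 60), k=st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_binomial_oracle(self, n, k):
        k = min(k, n)
        _, p = directionality_test(k, n - k)
        expected = sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        assert p == pytest.approx(expected, abs=1e-12)


class TestSelection:
    def _stats(self, **kw):
        base = dict(n_exposed=200, n_ab=150, rr=2.0, p_value=0.004, n_comparison_b_mean=10.0)
        base.update(kw)
        return PairStats(**base)

    def test_rr_at_most_one_excluded(self):
        cohort = make_cohort([("p", 1, 1950, [])])
        stats = {("A", "B"): self._stats(a="A", b="B", rr=0.9)}
        cfg = SamplingConfig(iterations=100, min_patients=100, **WINDOW)
        assert select_pairs(stats, cohort, cfg) == []

    def test_min_patient_floor(self):
        cohort = make_cohort([("p", 1, 1950, [])])
        stats = {("A", "B"): self._stats(a="A", b="B", n_ab=99)}
        cfg = SamplingConfig(iterations=100, min_patients=100, **WINDOW)
        assert select_pairs(stats, cohort, cfg) == []

    def test_directionality_keeps_majority_direction(self):
        # 12 patients A->B in window, 1 patient B->A: forward dominates
        specs = [(f"f{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(12)]
        specs += [("r0", 1, 1950, [("B", 0), ("A", 400)])]
        cohort = make_cohort(specs, n_age_groups=1)
        stats = {
            ("A", "B"): self._stats(a="A", b="B", n_ab=120),
            ("B", "A"): self._stats(a="B", b="A", n_ab=120, rr=1.5),
        }
        cfg = SamplingConfig(iterations=100, min_patients=100, **WINDOW)
        kept = select_pairs(stats, cohort, cfg)
        assert [(s.a, s.b) for s in kept] == [("A", "B")]
        assert kept[0].direction == FORWARD

    def test_balanced_bidirectional_pair_dropped(self):
        specs = [(f"f{i}", 1, 1950, [("A", 0), ("B", 400)]) for i in range(6)]
        specs += [(f"r{i}", 1, 1950, [("B", 0), ("A", 400)]) for i in range(5)]
        cohort = make_cohort(specs, n_age_groups=1)
        stats = {
            ("A", "B"): self._stats(a="A", b="B"),
            ("B", "A"): self._stats(a="B", b="A", rr=1.5),
        }
        cfg = SamplingConfig(iterations=100, min_patients=100, **WINDOW)
        assert select_pairs(stats, cohort, cfg) == []


class TestAdjustment:
    def test_bh_matches_reference_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.2])
        adj = adjust_pvalues(p, "bh")
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.2])

    def test_bonferroni(self):
        assert adjust_pvalues(np.array([0.01, 0.5]), "bonferroni") == pytest.approx([0.02, 1.0])

    def test_none_is_identity(self):
        p = np.array([0.3, 0.01])
        assert (adjust_pvalues(p, "none") == p).all()
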