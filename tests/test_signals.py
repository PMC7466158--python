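import math

import pytest

from ddiscreen.contingency import ContingencyTable4x2, Perspective, SubsetView, TripleKey
from ddiscreen.signals import (
    Algorithm,
    RorConfig,
    SubsetCriterion,
    Z975,
    additive_signal,
    chi_square_signal,
    g11_from_f,
    hypothetical_truth,
    multiplicative_signal,
    omega_signal,
    ror,
    subset_signal,
)

from .conftest import EVENT, table_from_f


def view(n11, n10, n01, n00):
    return SubsetView(n11, n10, n01, n00, Perspective.WITHIN_D1_USERS)


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------

class TestRor:
    def test_oracle_example(self):
        # frozen from an independent evaluation of the estimate and CI:
        # OR = 20*800/(80*100) = 2; se = sqrt(1/20+1/80+1/100+1/800)
        r = ror(view(20, 80, 100, 800))
        assert r.computable
        assert r.ror == pytest.approx(2.0)
        assert r.ci_lower == pytest.approx(1.17454, abs=1e-4)
        assert r.ci_upper == pytest.approx(3.40557, abs=1e-4)

    def test_identity_case_symmetric_ci(self):
        r = ror(view(50, 50, 50, 50))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_lower * r.ci_upper == pytest.approx(1.0)

    def test_zero_cell_not_computable(self):
        r = ror(view(0, 80, 100, 800))
        assert not r.computable
        assert math.isnan(r.ror)

    def test_haldane_correction_makes_zero_cell_computable(self):
        r = ror(view(0, 80, 100, 800), RorConfig(haldane=True))
        assert r.computable and r.ror > 0

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            ror(view(-1, 1, 1, 1))

    def test_ci_brackets_point_estimate(self):
        r = ror(view(7, 13, 29, 151))
        assert r.ci_lower <= r.ror <= r.ci_upper


# ---------------------------------------------------------------------------
# subset criteria
# ---------------------------------------------------------------------------

def _table(n111, n110, n101, n100, n011, n010, n001=10, n000=1000):
    return ContingencyTable4x2(n111, n110, n101, n100, n011, n010, n001, n000)


class TestSubsetSignal:
    BOTH = _table(30, 70, 10, 890, 10, 890)       # strong in both subsets
    ONE = _table(30, 70, 10, 890, 100, 200)       # strong within D1 only
    NEITHER = _table(30, 70, 100, 200, 100, 200)  # weak in both

    def test_both_subsets_signal(self):
        prev = subset_signal(self.BOTH, SubsetCriterion.PREVIOUS)
        new = subset_signal(self.BOTH, SubsetCriterion.NEW)
        assert prev.signal and new.signal
        assert prev.algorithm is Algorithm.SUBSET_PREVIOUS
        assert new.algorithm is Algorithm.SUBSET_NEW

    def test_single_subset_splits_criteria(self):
        assert subset_signal(self.ONE, SubsetCriterion.PREVIOUS).signal
        assert not subset_signal(self.ONE, SubsetCriterion.NEW).signal

    def test_neither_subset_signals(self):
        assert not subset_signal(self.NEITHER, SubsetCriterion.PREVIOUS).signal
        assert not subset_signal(self.NEITHER, SubsetCriterion.NEW).signal

    def test_detail_carries_both_rors(self):
        d = subset_signal(self.ONE, SubsetCriterion.NEW).detail
        assert d.signal_d1 and not d.signal_d2
        assert d.within_d1.ror > 1 > d.within_d2.ror

    def test_min_n11_floor(self):
        config = RorConfig(min_n11=31)
        assert not subset_signal(self.BOTH, SubsetCriterion.NEW, config).signal

    def test_pure_function(self):
        a = subset_signal(self.BOTH, SubsetCriterion.NEW)
        b = subset_signal(self.BOTH, SubsetCriterion.NEW)
        assert a == b


# ---------------------------------------------------------------------------
# Omega shrinkage measure
# ---------------------------------------------------------------------------

class TestOmega:
    def test_identity_when_observed_equals_expected(self):
        # f00 = f10 = f01 = 0.2 so g11 = 0.2 and E111 = 0.2 * 50 = 10 = n111
        t = ContingencyTable4x2(10, 40, 20, 80, 20, 80, 20, 80)
        v = omega_signal(t)
        assert v.detail.e111 == pytest.approx(10.0)
        assert v.detail.omega == pytest.approx(0.0, abs=1e-12)
        assert not v.signal

    def test_hand_evaluated_example(self):
        # f00 = f10 = f01 = 0.1, n11p = 100, n111 = 30:
        # g11 = 0.1, E111 = 10, Omega = log2(30.5/10.5),
        # Omega025 = Omega - z/(ln2 * sqrt(30))
        t = ContingencyTable4x2(30, 70, 10, 90, 10, 90, 10, 90)
        v = omega_signal(t)
        assert v.detail.g11 == pytest.approx(0.1)
        assert v.detail.e111 == pytest.approx(10.0)
        assert v.detail.omega == pytest.approx(1.53842, abs=1e-4)
        assert v.detail.omega025 == pytest.approx(1.02217, abs=2e-4)
        assert v.signal

    def test_g11_falls_back_to_max_f00_f01(self):
        # f10 < f00 -> g11 = max(f00, f01) exactly
        assert g11_from_f(0.2, 0.1, 0.35) == pytest.approx(0.35, abs=1e-12)
        assert g11_from_f(0.2, 0.1, 0.05) == pytest.approx(0.2, abs=1e-12)

    def test_g11_falls_back_to_max_f00_f10(self):
        assert g11_from_f(0.2, 0.4, 0.1) == pytest.approx(0.4, abs=1e-12)

    def test_g11_all_equal(self):
        assert g11_from_f(0.3, 0.3, 0.3) == pytest.approx(0.3, abs=1e-12)

    def test_zero_marginal_not_computable(self):
        t = ContingencyTable4x2(1, 1, 1, 1, 0, 0, 1, 1)
        v = omega_signal(t)
        assert not v.signal and not v.detail.computable

    def test_n111_zero_never_signals(self):
        t = ContingencyTable4x2(0, 50, 5, 95, 5, 95, 5, 95)
        v = omega_signal(t)
        assert v.detail.omega025 == -math.inf
        assert not v.signal

    def test_f_cell_one_is_clamped(self):
        t = ContingencyTable4x2(5, 5, 3, 0, 2, 8, 1, 9)  # f10 = 1
        v = omega_signal(t)
        assert v.detail.computable and v.detail.clamped
        assert math.isfinite(v.detail.omega)

    def test_omega025_below_omega_when_n111_positive(self):
        t = ContingencyTable4x2(30, 70, 10, 90, 10, 90, 10, 90)
        v = omega_signal(t)
        assert v.detail.omega025 < v.detail.omega


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------

class TestAdditive:
    def test_no_interaction_identity(self):
        t = table_from_f(100, 0.2, 100, 0.2, 100, 0.2, 100, 0.2)
        v = additive_signal(t)
        assert v.detail.delta == pytest.approx(0.0, abs=1e-12)
        assert not v.signal

    def test_hand_evaluated_example(self):
        # delta = 0.30 - 0.05 - 0.05 + 0.01 = 0.21;
        # var = (0.21 + 2*0.0475 + 0.0099)/1000 -> se ~ 0.0177454
        t = table_from_f(1000, 0.30, 1000, 0.05, 1000, 0.05, 1000, 0.01)
        v = additive_signal(t)
        assert v.detail.delta == pytest.approx(0.21)
        assert v.detail.se == pytest.approx(0.0177454, abs=1e-6)
        assert v.signal

    def test_doubling_counts_shrinks_ci_at_fixed_delta(self):
        small = table_from_f(100, 0.30, 100, 0.05, 100, 0.05, 100, 0.01)
        big = table_from_f(200, 0.30, 200, 0.05, 200, 0.05, 200, 0.01)
        vs, vb = additive_signal(small), additive_signal(big)
        assert vb.detail.delta == pytest.approx(vs.detail.delta)
        assert vb.detail.se < vs.detail.se

    def test_zero_marginal_flagged(self):
        t = ContingencyTable4x2(0, 0, 1, 9, 1, 9, 1, 9)
        v = additive_signal(t)
        assert not v.signal and not v.detail.computable


class TestMultiplicative:
    def test_multiplicative_null_identity(self):
        # f11/f10 = f01/f00 -> R = 1
        t = table_from_f(100, 0.25, 100, 0.05, 100, 0.25, 100, 0.05)
        v = multiplicative_signal(t)
        assert v.detail.ratio == pytest.approx(1.0)
        assert not v.signal

    def test_hand_evaluated_example_signals_at_large_n(self):
        # R = (0.5 * 0.01)/(0.05 * 0.05) = 2; at nij+ = 5000 the log-scale
        # variance is 0.0276 so the lower bound exp(ln2 - z*0.16613) ~ 1.4442
        t = table_from_f(5000, 0.50, 5000, 0.05, 5000, 0.05, 5000, 0.01)
        v = multiplicative_signal(t)
        assert v.detail.ratio == pytest.approx(2.0)
        assert v.detail.ci_lower == pytest.approx(1.44418, abs=1e-4)
        assert v.signal

    def test_same_cells_at_small_n_do_not_signal(self):
        # identical proportions at nij+ = 500: variance 0.276, lower ~ 0.7142
        t = table_from_f(500, 0.50, 500, 0.05, 500, 0.05, 500, 0.01)
        v = multiplicative_signal(t)
        assert v.detail.ratio == pytest.approx(2.0)
        assert v.detail.ci_lower == pytest.approx(0.71425, abs=1e-4)
        assert not v.signal

    def test_symmetric_under_drug_swap(self):
        t = table_from_f(100, 0.4, 200, 0.1, 400, 0.05, 500, 0.02)
        assert multiplicative_signal(t).detail.ratio == pytest.approx(
            multiplicative_signal(t.swap_drugs()).detail.ratio
        )

    def test_zero_f_cell_flagged(self):
        t = ContingencyTable4x2(0, 100, 5, 95, 5, 95, 5, 95)
        v = multiplicative_signal(t)
        assert not v.signal and not v.detail.computable


class TestChiSquare:
    def test_excess_signals(self):
        # e = 200 * (0.1*0.1/0.05) = 40; chi2 = 39.5^2 * (1/40 + 1/160)
        t = ContingencyTable4x2(80, 120, 100, 900, 100, 900, 50, 950)
        v = chi_square_signal(t)
        assert v.detail.expected == pytest.approx(40.0)
        assert v.detail.statistic == pytest.approx(48.7578125, abs=1e-6)
        assert v.signal

    def test_observed_at_expectation_is_null(self):
        t = ContingencyTable4x2(40, 160, 100, 900, 100, 900, 50, 950)
        v = chi_square_signal(t)
        assert v.detail.statistic == pytest.approx(0.0, abs=1e-2)
        assert not v.signal

    def test_deficit_blocked_by_one_sided_guard(self):
        t = ContingencyTable4x2(10, 190, 100, 900, 100, 900, 50, 950)
        v = chi_square_signal(t)
        assert v.detail.statistic > 3.841
        assert not v.signal

    def test_degenerate_expected_flagged(self):
        t = ContingencyTable4x2(5, 5, 0, 10, 0, 10, 5, 5)  # e = 0
        v = chi_square_signal(t)
        assert not v.signal and not v.detail.computable


# ---------------------------------------------------------------------------
# surrogate truth
# ---------------------------------------------------------------------------

class TestHypotheticalTruth:
    A = TripleKey("a", "b", EVENT)
    B = TripleKey("b", "c", EVENT)
    C = TripleKey("c", "d", EVENT)

    def test_set_intersection(self):
        got = hypothetical_truth({self.A, self.B}, {self.B, self.C}, {self.B})
        assert got == {self.B}

    def test_empty_input_gives_empty_truth(self):
        assert hypothetical_truth(set(), {self.B}, {self.B}) == set()

    def test_mismatched_universes_rejected(self):
        from ddiscreen.signals import SignalVerdict

        m1 = {self.A: SignalVerdict(Algorithm.ADDITIVE, True)}
        m2 = {self.B: SignalVerdict(Algorithm.MULTIPLICATIVE, True)}
        m3 = {self.A: SignalVerdict(Algorithm.CHI_SQUARE, True)}
        with pytest.raises(ValueError, match="universe"):
            hypothetical_truth(m1, m2, m3)

    def test_matches_brute_force_on_random_universe(self):
        import numpy as np

        rng = np.random.default_rng(5)
        universe = [TripleKey(f"d{i:02d}", "zz", EVENT) for i in range(40)]
        sets = [
            {t for t in universe if rng.random() < 0.5} for _ in range(3)
        ]
        expected = {t for t in universe if all(t in s for s in sets)}
        assert hypothetical_truth(*sets) == expected
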