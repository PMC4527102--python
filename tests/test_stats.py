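"""Differential statistics: SpI, R_SC, G-test, exact tests, classification."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcdiff import (
    DegenerateTableError,
    InconsistentSummaryError,
    LABEL_CASE,
    LABEL_CONTROL,
    LABEL_NS,
    ParameterError,
    ProteinGroupSummary,
    Thresholds,
    UndefinedInputError,
    classify_protein,
    fisher_exact_2x2,
    g_test_yates,
    mann_whitney_groups,
    rsc_log2_ratio,
    run_differential_table,
    spectral_index,
)
from spcdiff.datasets import reference_summaries, reference_table

from conftest import build_matrix
from oracles import fisher_two_sided_enum, g_yates_mp, mw_u_brute


def make_summary(n_a, n_b, d_a, d_b, t_a=10_000, t_b=10_000, cap_a=5, cap_b=15):
    return ProteinGroupSummary(
        entry_name="P", n_a=n_a, n_b=n_b, d_a=d_a, d_b=d_b,
        t_a=t_a, t_b=t_b, cap_n_a=cap_a, cap_n_b=cap_b,
    )


def swap_groups(s: ProteinGroupSummary) -> ProteinGroupSummary:
    return ProteinGroupSummary(
        entry_name=s.entry_name, n_a=s.n_b, n_b=s.n_a, d_a=s.d_b, d_b=s.d_a,
        t_a=s.t_b, t_b=s.t_a, cap_n_a=s.cap_n_b, cap_n_b=s.cap_n_a,
    )


def summaries_strategy():
    @st.composite
    def _build(draw):
        cap_a = draw(st.integers(1, 8))
        cap_b = draw(st.integers(1, 20))
        n_a = draw(st.integers(0, 300))
        n_b = draw(st.integers(0, 300))
        d_a = draw(st.integers(1, cap_a)) if n_a > 0 else 0
        d_b = draw(st.integers(1, cap_b)) if n_b > 0 else 0
        if n_a + n_b == 0:
            n_b, d_b = 1, 1
        t_a = n_a + draw(st.integers(1, 5000))
        t_b = n_b + draw(st.integers(1, 5000))
        return make_summary(n_a, n_b, d_a, d_b, t_a, t_b, cap_a, cap_b)

    return _build()


class TestSpectralIndex:
    def test_reference_rows_reproduced_to_3dp(self):
        """All 31 printed SpI values of the reference comparison."""
        df = reference_table()
        for s, printed in zip(reference_summaries(), df.spi):
            assert round(spectral_index(s), 3) == pytest.approx(printed, abs=1e-9)

    def test_case_only_boundary_is_one(self):
        s = make_summary(0, 50, 0, 15)
        assert spectral_index(s) == 1.0
        assert spectral_index(swap_groups(s)) == -1.0

    def test_undefined_for_all_zero(self):
        with pytest.raises(UndefinedInputError):
            spectral_index(make_summary(0, 0, 0, 0))

    def test_reduces_to_detection_fraction_when_control_absent(self):
        s = make_summary(0, 37, 0, 10)
        assert spectral_index(s) == pytest.approx(10 / 15)

    @settings(deadline=None, max_examples=200)
    @given(summaries_strategy())
    def test_range_and_antisymmetry(self, s):
        spi = spectral_index(s)
        assert -1.0 <= spi <= 1.0
        assert spectral_index(swap_groups(s)) == pytest.approx(-spi, abs=1e-12)


class TestRsc:
    def test_zero_for_symmetric_input(self):
        assert rsc_log2_ratio(make_summary(10, 10, 1, 1, 1000, 1000)) == 0.0

    def test_matches_exact_rational_arithmetic(self):
        # independent route: exact rationals, single final log2
        s = make_summary(4, 87, 2, 12, t_a=2000, t_b=6000)
        f = Fraction(1, 2)
        ratio = ((87 + f) / (4 + f)) * ((2000 - 4 + f) / (6000 - 87 + f))
        expected = math.log2(float(ratio))
        assert rsc_log2_ratio(s, f=0.5) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_totals_rejected(self):
        bad = make_summary(4, 87, 2, 12, t_a=2000, t_b=87)
        object.__setattr__(bad, "t_b", 50)  # bypass constructor check
        with pytest.raises(InconsistentSummaryError):
            rsc_log2_ratio(bad, f=0.5)

    def test_bad_pseudocount(self):
        with pytest.raises(ParameterError):
            rsc_log2_ratio(make_summary(1, 1, 1, 1), f=0.0)

    @settings(deadline=None, max_examples=200)
    @given(summaries_strategy())
    def test_antisymmetry_under_group_swap(self, s):
        assert rsc_log2_ratio(swap_groups(s)) == pytest.approx(
            -rsc_log2_ratio(s), abs=1e-10
        )

    def test_monotone_in_case_count(self):
        values = [
            rsc_log2_ratio(make_summary(10, n_b, 2, min(n_b, 15) or 1, 2000, 2000))
            for n_b in range(1, 200, 10)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestGTestYates:
    def test_observed_equals_expected(self):
        g, p = g_test_yates(5, 5, 50, 50)
        assert g == 0.0 and p == 1.0

    def test_against_arbitrary_precision_oracle(self):
        g, p = g_test_yates(10, 40, 90, 60)
        g_mp, p_mp = g_yates_mp(10, 40, 90, 60)
        assert g == pytest.approx(g_mp, rel=1e-12)
        assert p == pytest.approx(p_mp, rel=1e-10)

    def test_random_tables_against_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 400, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            g, p = g_test_yates(int(a), int(b), int(c), int(d))
            g_mp, p_mp = g_yates_mp(int(a), int(b), int(c), int(d))
            assert g == pytest.approx(g_mp, rel=1e-10, abs=1e-12)
            assert p == pytest.approx(p_mp, rel=1e-8, abs=1e-300)

    def test_small_deviation_contributes_zero(self):
        # |O - E| <= 0.5 in every cell: correction cancels the deviation
        g, p = g_test_yates(50, 50, 51, 50)
        assert g == 0.0 and p == 1.0

    @staticmethod
    def _g_uncorrected(a, b, c, d):
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        return 2 * (obs * np.log(obs / exp)).sum()

    def test_large_count_limit_close_to_uncorrected(self):
        # the relative size of the correction is unbounded near the null
        # (uncorrected G -> 0), so the 10% agreement is asserted for
        # tables with a clear departure from independence
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 50:
            a, b, c, d = (int(x) for x in rng.integers(50, 500, size=4))
            g_raw = self._g_uncorrected(a, b, c, d)
            if g_raw < 8.0:
                continue
            g, _ = g_test_yates(a, b, c, d)
            assert abs(g - g_raw) / g_raw < 0.10
            checked += 1

    def test_correction_vanishes_as_table_scales(self):
        base = (10, 40, 90, 60)
        rels = []
        for scale in (1, 10, 100):
            cells = tuple(x * scale for x in base)
            g, _ = g_test_yates(*cells)
            g_raw = self._g_uncorrected(*cells)
            rels.append(abs(g - g_raw) / g_raw)
        assert rels[0] > rels[1] > rels[2]
        assert rels[2] < 1e-3

    @pytest.mark.parametrize("table", [(0, 0, 5, 5), (5, 5, 0, 0), (0, 5, 0, 5)])
    def test_zero_margin_rejected(self, table):
        with pytest.raises(DegenerateTableError):
            g_test_yates(*table)

    def test_negative_cell_rejected(self):
        with pytest.raises(ParameterError):
            g_test_yates(-1, 5, 5, 5)


class TestFisher:
    def test_fully_separated_table(self):
        assert fisher_exact_2x2(0, 5, 5, 0) == pytest.approx(2 / 252, rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_small_margin_tables_against_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2(int(a), int(b), int(c), int(d)) == pytest.approx(
                fisher_two_sided_enum(int(a), int(b), int(c), int(d)), rel=1e-8
            )


class TestMannWhitney:
    def test_fully_tied(self):
        u, p = mann_whitney_groups([3, 3, 3], [3, 3, 3])
        assert u == 4.5 and p == 1.0

    def test_separated_small_groups(self):
        u, p = mann_whitney_groups([0, 0, 1], [5, 6, 7])
        assert u == 9.0
        assert p == pytest.approx(0.1)

    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ctrl = rng.integers(0, 6, size=5).tolist()
            case = rng.integers(0, 6, size=7).tolist()
            u, _ = mann_whitney_groups(ctrl, case)
            assert u == mw_u_brute(ctrl, case)

    def test_exact_close_to_asymptotic_without_ties(self):
        rng = np.random.default_rng(9)
        import scipy.stats as sps

        for _ in range(20):
            vals = rng.permutation(np.arange(16, dtype=float))
            ctrl, case = vals[:8], vals[8:]
            _, p_exact = mann_whitney_groups(ctrl, case)
            p_asym = sps.mannwhitneyu(
                case, ctrl, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_groups([], [1, 2])


class TestClassification:
    @pytest.mark.parametrize(
        "p_g,rsc,label,top",
        [
            (1.929e-6, 2.261, LABEL_CASE, True),
            (5.517e-5, -2.170, LABEL_CONTROL, True),
            (0.5, 3.0, LABEL_NS, False),
            (0.01, 1.5, LABEL_CASE, False),
            (0.01, 0.5, LABEL_NS, False),
            (1e-5, -3.0, LABEL_CONTROL, True),
        ],
    )
    def test_joint_rule(self, p_g, rsc, label, top):
        got_label, got_top, _ = classify_protein(spi=0.0, rsc=rsc, p_g=p_g)
        assert got_label == label
        assert got_top is top

    def test_spi_flag_independent_of_label(self):
        _, _, flag = classify_protein(spi=0.5, rsc=0.0, p_g=1.0)
        assert flag
        _, _, flag = classify_protein(spi=0.4, rsc=0.0, p_g=1.0)
        assert not flag

    def test_threshold_invariants_enforced(self):
        with pytest.raises(ParameterError):
            Thresholds(alpha_g=0.05, alpha_top=0.1)
        with pytest.raises(ParameterError):
            Thresholds(rsc_cut=2.0, rsc_top=1.0)


class TestRunDifferentialTable:
    def test_sorted_by_descending_spi(self, small_matrix):
        records = run_differential_table(small_matrix, validate=False)
        spis = [r.spi for r in records if r.spi is not None]
        assert spis == sorted(spis, reverse=True)

    def test_every_protein_appears_once(self, small_matrix):
        records = run_differential_table(small_matrix, validate=False)
        assert sorted(r.entry_name for r in records) == sorted(
            small_matrix.entry_names
        )

    def test_never_observed_carries_reason(self, small_matrix):
        records = run_differential_table(small_matrix, validate=False)
        (skipped,) = [r for r in records if r.skip_reason]
        assert skipped.skip_reason == "never_observed"
        assert skipped.label == LABEL_NS and skipped.p_g is None

    def test_single_protein_table_degenerate(self):
        m = build_matrix(np.array([[5, 9]]), n_control=1, n_case=1)
        (record,) = run_differential_table(m, validate=False)
        assert record.skip_reason == "degenerate_table"
        assert record.p_g is None and record.spi is not None

    def test_validation_pvalues_populated(self, small_matrix):
        records = run_differential_table(small_matrix, validate=True)
        tested = [r for r in records if r.p_g is not None]
        assert all(r.p_fisher is not None and r.p_mw is not None for r in tested)
        assert all(0 < r.p_fisher <= 1 and 0 < r.p_mw <= 1 for r in tested)

    def test_bh_column_attached_but_not_classifying(self, small_matrix):
        records = run_differential_table(small_matrix, validate=False)
        tested = [r for r in records if r.p_g is not None]
        assert all(r.bh_fdr is not None for r in tested)
        assert all(r.bh_fdr >= r.p_g - 1e-15 for r in tested)
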