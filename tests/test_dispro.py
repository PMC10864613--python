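"""Disproportionality statistics, signal criteria, consensus and ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvsignals.dispro import (
    ContingencyTable,
    build_contingency,
    compute_bcpnn,
    compute_prr,
    compute_ror,
    compute_stats,
    contingency_all_terms,
    evaluate_signal,
    flag_unexpected,
    rank_results,
    signal_table,
)

cells = st.integers(min_value=1, max_value=5000)


class TestContingency:
    EVENTS = pd.DataFrame({
        "PRIMARYID": ["1", "1", "2", "2"],
        "pt": ["ptP", "ptQ", "ptP", "ptQ"],
        "soc": ["s1", "s1", "s1", "s1"],
    })

    def test_full_enumeration_toy(self):
        t = build_contingency(self.EVENTS.iloc[:2], self.EVENTS.iloc[2:], "ptP")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_term_gives_zero_a(self):
        t = build_contingency(self.EVENTS.iloc[:2], self.EVENTS.iloc[2:], "ptZ")
        assert t.a == 0 and t.b == 2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=0, c=0, d=1)
        with pytest.raises(ValueError):
            ContingencyTable(a=0, b=0, c=0, d=0)

    def test_vectorised_tables_partition_target_events(self, small_analysis):
        tables = contingency_all_terms(small_analysis.events,
                                       small_analysis.background_events)
        assert tables["a"].sum() == len(small_analysis.events)
        assert ((tables["a"] + tables["b"]) == len(small_analysis.events)).all()
        assert ((tables["c"] + tables["d"]) == len(small_analysis.background_events)).all()


class TestROR:
    def test_symmetric_table(self):
        ror, low, high = compute_ror(1, 1, 1, 1)
        assert ror == pytest.approx(1.0)
        assert low == pytest.approx(np.exp(-3.92), rel=1e-3)
        assert high == pytest.approx(np.exp(3.92), rel=1e-3)

    def test_hand_value(self):
        ror, low, high = compute_ror(10, 90, 100, 9900)
        assert ror == pytest.approx(11.0)
        assert low < 11.0 < high

    def test_zero_cell_undefined_without_correction(self):
        ror, low, high = compute_ror(0, 10, 10, 100)
        assert np.isnan(ror) and np.isnan(low)

    def test_zero_cell_defined_with_haldane_correction(self):
        ror, low, high = compute_ror(0, 10, 10, 100, correction=True)
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))


class TestPRR:
    def test_independence(self):
        prr, chi2 = compute_prr(1, 1, 1, 1)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_value(self):
        prr, _ = compute_prr(10, 90, 100, 9900)
        assert prr == pytest.approx(10.0)

    def test_chi2_matches_expected_count_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 2000, 4)
            _, chi2 = compute_prr(a, b, c, d)
            ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_yates_variant_is_smaller(self):
        _, plain = compute_prr(10, 90, 100, 9900)
        _, corrected = compute_prr(10, 90, 100, 9900, yates=True)
        assert corrected < plain


class TestBCPNN:
    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_raw_ic_zero_on_symmetric_table(self, k):
        ic, _, _ = compute_bcpnn(k, k, k, k)
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        ic, _, _ = compute_bcpnn(10, 90, 100, 9900)
        assert ic == pytest.approx(np.log2(10 * 10100 / (110 * 100)), abs=1e-9)
        assert ic == pytest.approx(3.199, abs=1e-3)

    def test_zero_a_closed_form_is_finite(self):
        ic, ic025, ic975 = compute_bcpnn(0, 10, 10, 100)
        assert np.isfinite(ic) and np.isfinite(ic025) and ic025 < 0

    def test_interval_orders(self):
        _, ic025, ic975 = compute_bcpnn(20, 200, 100, 9000)
        assert ic025 < ic975

    def test_closed_form_tracks_monte_carlo(self):
        # quick spot check; the full >=5-cells sweep runs in the acceptance suite
        for cells4 in [(5, 5, 5, 5), (10, 90, 100, 9900), (37, 411, 502, 12000)]:
            _, lo_c, hi_c = compute_bcpnn(*cells4, method="closed_form")
            _, lo_m, hi_m = compute_bcpnn(*cells4, method="monte_carlo",
                                          n_draws=50_000, seed=1)
            assert lo_c == pytest.approx(lo_m, abs=0.12)


class TestCriteria:
    def test_small_a_blocks_ror_flag(self):
        # huge ROR but only 2 target reports
        stats = compute_stats(ContingencyTable(2, 10, 1, 10000))
        f_ror, f_prr, f_b, cons = evaluate_signal(2, stats.ror_low, stats.prr,
                                                  stats.chi2, stats.ic025)
        assert not f_ror and not cons

    def test_worked_table_flags_prr(self):
        stats = compute_stats(ContingencyTable(10, 90, 100, 9900))
        _, f_prr, _, _ = evaluate_signal(10, stats.ror_low, stats.prr,
                                         stats.chi2, stats.ic025)
        assert f_prr

    def test_consensus_is_conjunction(self):
        f = evaluate_signal(np.array([10, 10]), np.array([2.0, 2.0]),
                            np.array([3.0, 3.0]), np.array([10.0, 10.0]),
                            np.array([0.5, -0.5]))
        flag_ror, flag_prr, flag_bcpnn, consensus = f
        assert consensus[0] and not consensus[1]
        assert (consensus == (flag_ror & flag_prr & flag_bcpnn)).all()

    def test_undefined_stats_never_flag(self):
        f_ror, f_prr, f_b, cons = evaluate_signal(5, np.nan, np.nan, np.nan, np.nan)
        assert not (f_ror or f_prr or f_b or cons)


class TestExpectedness:
    RESULTS = pd.DataFrame({
        "term": ["Dizziness", "Renal impairment", "Nausea"],
        "a": [10, 8, 4],
        "consensus": [True, True, False],
    })

    def test_label_membership(self):
        out = flag_unexpected(self.RESULTS, ["dizziness"])
        assert out.set_index("term")["expectedness"].to_dict() == {
            "Dizziness": "expected",
            "Renal impairment": "unexpected",
            "Nausea": "n/a",
        }

    def test_missing_label_list_gives_unknown(self):
        out = flag_unexpected(self.RESULTS, None)
        assert (out["expectedness"] == "unknown").all()


class TestRanking:
    RESULTS = pd.DataFrame({
        "term": ["Renal impairment", "Dizziness", "Ataxia"],
        "a": [35, 58, 35],
        "ic025": [1.0, 0.5, 2.0],
    })

    def test_sort_by_case_number_with_alpha_tiebreak(self):
        out = rank_results(self.RESULTS, "case_number")
        assert list(out["term"]) == ["Dizziness", "Ataxia", "Renal impairment"]

    def test_sort_by_ic025(self):
        out = rank_results(self.RESULTS, "ic025")
        assert list(out["term"]) == ["Ataxia", "Renal impairment", "Dizziness"]

    def test_empty(self):
        assert rank_results(self.RESULTS.iloc[:0], "case_number").empty


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_independence_iff_cross_products_equal(self, a, b, c, d):
        ror, _, _ = compute_ror(a, b, c, d)
        _, chi2 = compute_prr(a, b, c, d)
        if a * d == b * c:
            assert ror == pytest.approx(1.0) and chi2 == pytest.approx(0.0, abs=1e-9)
        else:
            assert chi2 > 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.integers(1, 500), b=cells, c=cells, d=cells)
    def test_statistics_strictly_increase_in_a(self, a, b, c, d):
        """ROR and PRR rise strictly with a everywhere; the raw IC provably
        can decrease once a dominates its margins (it inflates N and both
        margins), so its monotonicity is asserted in the sparse-signal
        regime a < min(b, c) where signal detection operates."""
        ror1, _, _ = compute_ror(a, b, c, d)
        ror2, _, _ = compute_ror(a + 1, b, c, d)
        prr1, _ = compute_prr(a, b, c, d)
        prr2, _ = compute_prr(a + 1, b, c, d)
        assert ror2 > ror1 and prr2 > prr1
        if a + 1 <= min(b, c):
            ic1 = compute_bcpnn(a, b, c, d)[0]
            ic2 = compute_bcpnn(a + 1, b, c, d)[0]
            assert ic2 > ic1


def test_signal_table_has_fixed_column_order(small_analysis):
    from pvsignals.dispro import RESULT_COLUMNS
    assert list(small_analysis.signals_pt.columns) == RESULT_COLUMNS
    # consensus set is a subset of each per-algorithm positive set
    df = small_analysis.signals_pt
    cons = df[df["consensus"]]
    assert cons["flag_ror"].all() and cons["flag_prr"].all() and cons["flag_bcpnn"].all()
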