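"""Time-to-onset computation, summaries and Weibull fitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import weibull_min

from conftest import make_caseset
from pvsignals.cohort import DrugDictionary, select_primary_suspect
from pvsignals.tto import (
    WeibullFit,
    classify_hazard,
    compute_tto,
    fit_weibull,
    period_histogram,
    summarize_tto,
)

DICT = DrugDictionary(generic="entrectinib", brands=["ROZLYTREK"])


def _cohort(event_dt, start_dt):
    cases = make_caseset(
        demo=[{"PRIMARYID": "1", "CASEID": "1", "FDA_DT": "20200301",
               "EVENT_DT": event_dt}],
        drug=[{"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS",
               "DRUGNAME": "ROZLYTREK"}],
        reac=[{"PRIMARYID": "1", "PT": "Dizziness"}],
        ther=[{"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": start_dt}],
    )
    return select_primary_suspect(cases, DICT)


class TestComputeTTO:
    def test_simple_interval(self):
        records, audit = compute_tto(_cohort("20200115", "20200101"))
        assert records.loc[0, "days"] == 14
        assert sum(audit.values()) == 0

    def test_onset_before_start_excluded(self):
        records, audit = compute_tto(_cohort("20191230", "20200101"))
        assert records.empty
        assert audit["onset_before_start"] == 1

    def test_same_day_onset_retained_as_zero(self):
        records, _ = compute_tto(_cohort("20200101", "20200101"))
        assert records.loc[0, "days"] == 0

    @pytest.mark.parametrize("event_dt, start_dt, reason", [
        ("", "20200101", "missing_event_dt"),
        ("202001", "20200101", "partial_event_dt"),
        ("20200115", "", "missing_start_dt"),
        ("20200115", "202001", "partial_start_dt"),
    ])
    def test_date_exclusion_reasons(self, event_dt, start_dt, reason):
        records, audit = compute_tto(_cohort(event_dt, start_dt))
        assert records.empty
        assert audit[reason] == 1

    def test_earliest_valid_start_used(self):
        cases = make_caseset(
            demo=[{"PRIMARYID": "1", "CASEID": "1", "EVENT_DT": "20200301"}],
            drug=[{"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS",
                   "DRUGNAME": "ROZLYTREK"}],
            reac=[{"PRIMARYID": "1", "PT": "Dizziness"}],
            ther=[{"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "202001"},
                  {"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20200215"},
                  {"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20200201"}],
        )
        cohort = select_primary_suspect(cases, DICT)
        records, _ = compute_tto(cohort)
        assert records.loc[0, "days"] == 29   # from 20200201, partial row ignored

    def test_exclusions_plus_records_conserve_cohort(self, small_analysis):
        total = len(small_analysis.tto_records) + sum(small_analysis.tto_audit.values())
        assert total == small_analysis.cohort.n_cases


class TestSummaries:
    def test_median_and_iqr(self):
        records = pd.DataFrame({"PRIMARYID": list("abc"), "days": [10, 20, 30]})
        out = summarize_tto(records)
        assert out.loc[0, "median"] == 20
        assert (out.loc[0, "q1"], out.loc[0, "q3"]) == (15, 25)

    def test_single_record(self):
        out = summarize_tto(pd.DataFrame({"PRIMARYID": ["a"], "days": [5]}))
        assert out.loc[0, ["median", "q1", "q3"]].tolist() == [5, 5, 5]

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        days = rng.integers(0, 400, 50)
        a = summarize_tto(pd.DataFrame({"PRIMARYID": range(50), "days": days}))
        b = summarize_tto(pd.DataFrame({"PRIMARYID": range(50), "days": days[::-1]}))
        pd.testing.assert_frame_equal(a, b)

    def test_histogram_bin_edges(self):
        records = pd.DataFrame({"PRIMARYID": ["a", "b"], "days": [0, 400]})
        hist = period_histogram(records)
        assert hist.set_index("period_days")["count"].to_dict() == {
            "0-30": 1, "31-60": 0, "61-90": 0, "91-180": 0, "181-360": 0, ">360": 1}
        assert hist["count"].sum() == 2

    def test_per_soc_grouping_reuses_case_events(self):
        records = pd.DataFrame({"PRIMARYID": ["1", "2"], "days": [10, 30]})
        events = pd.DataFrame({"PRIMARYID": ["1", "1", "2"],
                               "soc": ["SOC-A", "SOC-B", "SOC-A"]})
        out = summarize_tto(records, events=events, group_by="soc")
        by = out.set_index("group")
        assert by.loc["SOC-A", "n"] == 2 and by.loc["SOC-B", "n"] == 1


class TestWeibull:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        days = np.round(weibull_min.rvs(0.56, scale=30, size=500, random_state=rng))
        fit = fit_weibull(pd.DataFrame({"PRIMARYID": range(500), "days": days}))
        assert fit.converged
        assert fit.shape == pytest.approx(0.56, rel=0.15)
        assert fit.shape_ci[0] < fit.shape < fit.shape_ci[1]
        assert fit.scale_ci[0] < fit.scale < fit.scale_ci[1]

    def test_matches_scipy_mle_oracle(self):
        rng = np.random.default_rng(5)
        x = weibull_min.rvs(0.8, scale=45, size=400, random_state=rng)
        fit = fit_weibull(x)
        c_ref, _, scale_ref = weibull_min.fit(x, floc=0)
        assert fit.shape == pytest.approx(c_ref, rel=1e-3)
        assert fit.scale == pytest.approx(scale_ref, rel=1e-3)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            fit_weibull(np.arange(5))

    def test_degenerate_sample_is_nonconverged_not_crash(self):
        fit = fit_weibull(np.full(20, 7.0))
        assert not fit.converged
        assert fit.hazard_class == "indeterminate"

    def test_zero_days_shifted_not_dropped(self):
        rng = np.random.default_rng(9)
        days = np.round(weibull_min.rvs(0.7, scale=20, size=300, random_state=rng))
        fit = fit_weibull(days)
        assert fit.n_used == 300
        assert fit.converged


class TestHazardClassification:
    def _fit(self, shape, lo, hi):
        return WeibullFit(shape=shape, shape_ci=(lo, hi), scale=30.0,
                          scale_ci=(20.0, 40.0), n_used=100, log_likelihood=0.0)

    @pytest.mark.parametrize("shape, lo, hi, expected", [
        (0.56, 0.51, 0.61, "early-failure"),
        (1.0, 0.9, 1.1, "random"),
        (1.4, 1.2, 1.6, "wear-out"),
    ])
    def test_ci_based_classes(self, shape, lo, hi, expected):
        assert self._fit(shape, lo, hi).hazard_class == expected
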