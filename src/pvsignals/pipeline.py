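"""End-to-end orchestration: ingest → dedup → cohort → signals → TTO.

The per-drug quarter window is applied *after* deduplication, so a case
re-submitted across window boundaries is first reduced to its most recent
version and only then tested against the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import (
    Cohort,
    DrugDictionary,
    exclude_indication_terms,
    explode_events,
    observed_indication_terms,
    select_primary_suspect,
)
from .config import DrugConfig, StatsConfig
from .dedup import deduplicate
from .dispro import signal_table
from .io import CaseSet, TableBundle, assemble_cases, quarter_range
from .tto import WeibullFit, compute_tto, fit_weibull, period_histogram, summarize_tto

__all__ = ["DrugAnalysis", "analyze_drug", "prepare_cases"]


@dataclass
class DrugAnalysis:
    """Everything the pipeline derives for one target drug."""

    cohort: Cohort
    events: pd.DataFrame                  # cohort events after indication exclusion
    background_events: pd.DataFrame
    signals_pt: pd.DataFrame
    signals_soc: pd.DataFrame
    tto_records: pd.DataFrame
    tto_audit: dict[str, int]
    tto_summary: pd.DataFrame
    tto_histogram: pd.DataFrame
    weibull: WeibullFit | None = None
    dedup_audit: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_indication_excluded: int = 0


def prepare_cases(bundles: dict[str, TableBundle]) -> tuple[CaseSet, pd.DataFrame]:
    """Assemble all quarters and deduplicate (window applied later, per drug)."""
    cases = assemble_cases(bundles)
    return deduplicate(cases)


def analyze_drug(
    cases: CaseSet,
    drug_cfg: DrugConfig,
    pt_to_soc: pd.Series | dict,
    stats: StatsConfig | None = None,
    dedup_audit: pd.DataFrame | None = None,
    seed: int = 0,
) -> DrugAnalysis:
    """Run cohort construction, signal detection and TTO for one drug.

    *cases* must already be deduplicated; the drug's quarter window is
    applied here.
    """
    stats = stats or StatsConfig()
    window = quarter_range(drug_cfg.window_start, drug_cfg.window_end)
    windowed = cases.filter_window(window)

    cohort = select_primary_suspect(windowed, drug_cfg.dictionary)
    all_events = explode_events(windowed, pt_to_soc)
    in_cohort = all_events["PRIMARYID"].isin(set(cohort.cases.primaryids()))
    target_events = all_events[in_cohort].reset_index(drop=True)
    background_events = all_events[~in_cohort].reset_index(drop=True)

    indication_terms = drug_cfg.indication_terms
    if indication_terms is None:
        indication_terms = observed_indication_terms(cohort)
    n_before = len(target_events)
    target_events = exclude_indication_terms(target_events, indication_terms)

    signals_pt = signal_table(
        target_events, background_events, level="PT",
        label_terms=drug_cfg.label_terms,
        correction=stats.continuity_correction, yates=stats.yates,
        bcpnn_method=stats.bcpnn_method, seed=seed)
    signals_soc = signal_table(
        target_events, background_events, level="SOC",
        label_terms=None,
        correction=stats.continuity_correction, yates=stats.yates,
        bcpnn_method=stats.bcpnn_method, seed=seed)

    tto_records, tto_audit = compute_tto(cohort)
    tto_summary = summarize_tto(tto_records)
    if not tto_records.empty:
        by_soc = summarize_tto(tto_records, events=target_events, group_by="soc")
        tto_summary = pd.concat([tto_summary, by_soc], ignore_index=True)
    histogram = period_histogram(tto_records)

    analysis = DrugAnalysis(
        cohort=cohort,
        events=target_events,
        background_events=background_events,
        signals_pt=signals_pt,
        signals_soc=signals_soc,
        tto_records=tto_records,
        tto_audit=tto_audit,
        tto_summary=tto_summary,
        tto_histogram=histogram,
        dedup_audit=dedup_audit if dedup_audit is not None else pd.DataFrame(),
        n_indication_excluded=n_before - len(target_events),
    )
    if len(tto_records) >= stats.tto_min_n:
        analysis.weibull = fit_weibull(tto_records, min_n=stats.tto_min_n)
    return analysis
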