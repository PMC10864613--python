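"""Shared fixtures: small synthetic datasets and hand-built case sets."""

from __future__ import annotations

import pandas as pd
import pytest

import pvsignals as pv
from pvsignals.config import DrugConfig
from pvsignals.cohort import DrugDictionary
from pvsignals.io import TABLE_COLUMNS, CaseSet, TableBundle
from pvsignals.synthetic import SyntheticScenario, generate


def make_table(name: str, rows: list[dict]) -> pd.DataFrame:
    """Build one quarterly table from partial row dicts (missing fields blank)."""
    cols = TABLE_COLUMNS[name]
    return pd.DataFrame([{c: str(r.get(c, "")) for c in cols} for r in rows],
                        columns=cols, dtype=object)


def make_caseset(demo=(), drug=(), reac=(), ther=(), indi=(), outc=()) -> CaseSet:
    tables = {"demo": make_table("demo", list(demo))}
    tables["demo"]["QUARTER"] = ""
    for name, rows in [("drug", drug), ("reac", reac), ("ther", ther),
                       ("indi", indi), ("outc", outc)]:
        tables[name] = make_table(name, list(rows))
    return CaseSet(**tables)


def make_bundle(demo=(), drug=(), reac=(), ther=(), indi=(), outc=()) -> TableBundle:
    return TableBundle(**{
        name: make_table(name, list(rows))
        for name, rows in [("demo", demo), ("drug", drug), ("reac", reac),
                           ("ther", ther), ("indi", indi), ("outc", outc)]
    })


TARGET_CONFIG = DrugConfig(
    dictionary=DrugDictionary(generic="entrectinib", brands=["ROZLYTREK"]),
    window_start="2019Q3",
    window_end="2023Q1",
)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    # small but non-trivial: every structural feature present
    return SyntheticScenario(n_reports=4000, seed=7, target_share=0.05)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    return generate(small_scenario)


@pytest.fixture(scope="session")
def small_cases(small_data):
    cases, audit = pv.prepare_cases(small_data.bundles)
    return cases, audit


@pytest.fixture(scope="session")
def small_analysis(small_cases, small_scenario):
    cases, audit = small_cases
    return pv.analyze_drug(cases, TARGET_CONFIG, small_scenario.pt_vocabulary,
                           dedup_audit=audit)
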