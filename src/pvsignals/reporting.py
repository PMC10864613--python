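"""Descriptive outputs: baseline demographics, annual counts, SOC profiles.

Percentages are rounded half-up to one decimal, the convention under which
published FAERS baseline tables recompute exactly from their integer counts.
Serious-outcome percentages are computed over the total number of outcome
*entries* (a case can carry several outcome codes), not over cases.
"""

from __future__ import annotations

import hashlib
import json
import platform
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import Cohort
from .io import (
    OUTCOME_CODES,
    REPORTER_TYPE_MAP,
    age_in_years,
    parse_full_dates,
    weight_in_kg,
)

__all__ = [
    "round_half_up",
    "percentage",
    "demographics_table",
    "annual_counts",
    "compare_soc_profiles",
    "check_percentages",
    "build_report",
]

AGE_BANDS = ["<18", "18-64", ">64", "Unknown"]
WEIGHT_BANDS = ["<80", "80-100", ">100", "Unknown"]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """count/denominator as a percent, half-up to *decimals* places."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * count / denominator, decimals)


def _block(labels: list[str], counts: list[int], denom: int, block: str) -> pd.DataFrame:
    return pd.DataFrame({
        "block": block,
        "label": labels,
        "count": counts,
        "pct": [percentage(c, denom) for c in counts],
    })


def demographics_table(cohort: Cohort, top_n: int = 5) -> pd.DataFrame:
    """Baseline characteristics of a PS cohort.

    One row per (block, label): age bands (<18, 18-64, >64 years), sex,
    weight bands (<80, 80-100, >100 kg), top-N reporter countries, reporter
    type, top-N indication terms, and serious outcomes.  Closed blocks (age,
    sex, weight, reporter type) always include an Unknown row so their
    counts sum to the cohort size; outcome percentages use the outcome-entry
    total as denominator.
    """
    demo = cohort.cases.demo
    n = len(demo)
    if n == 0:
        return pd.DataFrame(columns=["block", "label", "count", "pct"])
    parts = []

    age = age_in_years(demo["AGE"], demo["AGE_COD"])
    age_counts = [
        int((age < 18).sum()),
        int(((age >= 18) & (age <= 64)).sum()),
        int((age > 64).sum()),
        int(age.isna().sum()),
    ]
    parts.append(_block(AGE_BANDS, age_counts, n, "age"))

    sex = demo["SEX"].fillna("").astype(str).str.strip().str.upper()
    parts.append(_block(
        ["Female", "Male", "Unknown"],
        [int((sex == "F").sum()), int((sex == "M").sum()),
         int((~sex.isin(["F", "M"])).sum())],
        n, "sex"))

    wt = weight_in_kg(demo["WT"])
    parts.append(_block(
        WEIGHT_BANDS,
        [int((wt < 80).sum()), int(((wt >= 80) & (wt <= 100)).sum()),
         int((wt > 100).sum()), int(wt.isna().sum())],
        n, "weight"))

    country = demo["REPORTER_COUNTRY"].fillna("").astype(str).str.strip()
    top_countries = country[country != ""].value_counts().head(top_n)
    parts.append(_block(list(top_countries.index), [int(v) for v in top_countries], n, "country"))

    occp = demo["OCCP_COD"].fillna("").astype(str).str.strip().str.upper()
    rtype = occp.map(REPORTER_TYPE_MAP).fillna("Unknown").str.capitalize()
    parts.append(_block(
        ["Consumer", "Health professional", "Unknown"],
        [int((rtype == "Consumer").sum()),
         int((rtype == "Health professional").sum()),
         int((rtype == "Unknown").sum())],
        n, "reporter_type"))

    indi = cohort.cases.indi.merge(
        cohort.matched_drug_seq,
        left_on=["PRIMARYID", "INDI_DRUG_SEQ"], right_on=["PRIMARYID", "DRUG_SEQ"],
        how="inner")
    ind = indi["INDI_PT"].fillna("").astype(str).str.strip()
    top_ind = ind[ind != ""].value_counts().head(top_n)
    parts.append(_block(list(top_ind.index), [int(v) for v in top_ind], n, "indication"))

    outc = cohort.cases.outc["OUTC_COD"].fillna("").astype(str).str.strip().str.upper()
    outc = outc[outc.isin(OUTCOME_CODES)]
    n_entries = len(outc)
    counts = outc.value_counts()
    labels = [c for c in OUTCOME_CODES if c in counts.index]
    parts.append(_block(labels, [int(counts[c]) for c in labels], n_entries, "serious_outcome"))

    return pd.concat(parts, ignore_index=True)


def annual_counts(cohort: Cohort) -> pd.DataFrame:
    """Report counts keyed by calendar year of FDA_DT; missing → 'unknown'."""
    dt = parse_full_dates(cohort.cases.demo["FDA_DT"])
    year = dt.dt.year.astype("Int64").astype(str).where(dt.notna(), "unknown")
    counts = year.value_counts().sort_index()
    return pd.DataFrame({"year": counts.index, "count": counts.to_numpy()})


def compare_soc_profiles(events_a: pd.DataFrame, events_b: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson chi-square homogeneity test of two drugs' SOC compositions.

    SOCs with zero combined count are dropped.  Returns (statistic, p-value,
    degrees of freedom).  Raises for degenerate matrices (fewer than two
    SOCs or an empty drug margin).
    """
    ca = events_a["soc"].value_counts()
    cb = events_b["soc"].value_counts()
    socs = sorted(set(ca.index) | set(cb.index))
    mat = np.array([[int(ca.get(s, 0)) for s in socs],
                    [int(cb.get(s, 0)) for s in socs]])
    mat = mat[:, mat.sum(axis=0) > 0]
    if mat.shape[1] < 2 or (mat.sum(axis=1) == 0).any():
        raise ValueError("degenerate SOC count matrix: need two drugs x >=2 SOCs with events")
    res = chi2_contingency(mat, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def check_percentages(rows: pd.DataFrame) -> pd.DataFrame:
    """Verify printed percentages against their printed counts.

    *rows* needs columns ``count``, ``denominator``, ``printed_pct`` and
    optionally ``decimals`` (default 1).  Returns the rows augmented with
    ``recomputed_pct`` and ``consistent`` (printed equals recomputed at the
    stated precision, half-up).
    """
    out = rows.copy()
    decimals = out["decimals"] if "decimals" in out.columns else pd.Series(1, index=out.index)
    out["recomputed_pct"] = [
        percentage(int(c), int(d), int(k))
        for c, d, k in zip(out["count"], out["denominator"], decimals)
    ]
    out["consistent"] = np.isclose(out["recomputed_pct"], out["printed_pct"], atol=1e-9)
    return out


def build_report(
    outputs: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    audits: Mapping[str, Mapping[str, int]] | None = None,
) -> Path:
    """Write a deterministic report bundle: delimited tables + run manifest.

    *outputs* maps table name → DataFrame; each is written as
    ``<name>.csv``.  The manifest records library versions, a config hash,
    the seed, per-table row counts and any exclusion audits.  Missing
    upstream stages simply yield absent tables, which the manifest lists
    under ``unavailable``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row_counts = {}
    unavailable = []
    for name, df in outputs.items():
        if df is None:
            unavailable.append(name)
            continue
        df.to_csv(out_dir / f"{name}.csv", index=False)
        row_counts[name] = int(len(df))

    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "python": platform.python_version(),
        "pandas": pd.__version__,
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "tables": row_counts,
        "unavailable": sorted(unavailable),
        "audits": {k: dict(v) for k, v in (audits or {}).items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
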