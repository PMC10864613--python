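"""Published FAERS tabulations for the first-generation NTRK inhibitors.

These are the printed baseline and SOC-level tables from the public
pharmacovigilance literature on entrectinib and larotrectinib, transcribed
as data.  They serve two purposes: arithmetic consistency checks (per-SOC
case counts must sum to the drug-level PT totals; every printed percentage
must recompute from its printed count at the stated rounding), and as
realistic calibration anchors for the synthetic-data generator's defaults.

Three printed percentages are internally inconsistent with their own counts
(listed in :data:`KNOWN_PERCENTAGE_DISCREPANCIES`); the consistency suite
asserts that exactly those rows, and no others, fail to recompute.
"""

from __future__ import annotations

import pandas as pd

from .reporting import check_percentages

__all__ = [
    "COHORT_SIZES",
    "PT_TOTALS",
    "OUTCOME_ENTRY_TOTALS",
    "TTO_REPORT_COUNTS",
    "MEDIAN_TTO",
    "WEIBULL_SHAPE",
    "soc_case_numbers",
    "baseline_percentages",
    "soc_composition_percentages",
    "tto_period_percentages",
    "all_printed_percentages",
    "consistency_report",
    "KNOWN_PERCENTAGE_DISCREPANCIES",
]

#: deduplicated primary-suspect report counts per drug
COHORT_SIZES = {"entrectinib": 563, "larotrectinib": 524}

#: event-level preferred-term totals per drug (distinct PT per case)
PT_TOTALS = {"entrectinib": 1605, "larotrectinib": 1343}

#: total serious-outcome entries (a case can carry several outcome codes)
OUTCOME_ENTRY_TOTALS = {"entrectinib": 518, "larotrectinib": 420}

#: reports surviving the time-to-onset date filters
TTO_REPORT_COUNTS = {"entrectinib": 243, "larotrectinib": 113}

#: (median, Q1, Q3) onset days
MEDIAN_TTO = {"entrectinib": (16.0, 6.0, 86.5), "larotrectinib": (44.0, 7.0, 136.0)}

#: Weibull shape beta (point, CI low, CI high); both early-failure type
WEIBULL_SHAPE = {"entrectinib": (0.56, 0.51, 0.61), "larotrectinib": (0.73, 0.62, 0.84)}

_SOC_ROWS = [
    # (SOC name, entrectinib case number, larotrectinib case number)
    ("Nervous system disorders", 304, 199),
    ("General disorders and administration site conditions", 243, 248),
    ("Investigations", 136, 94),
    ("Gastrointestinal disorders", 120, 101),
    ("Injury, poisoning and procedural complications", 105, 102),
    ("Cardiac disorders", 100, 8),
    ("Respiratory, thoracic and mediastinal disorders", 95, 61),
    ("Renal and urinary disorders", 90, 21),
    ("Musculoskeletal and connective tissue disorders", 62, 78),
    ("Infections and infestations", 59, 29),
    ("Metabolism and nutrition disorders", 47, 26),
    ("Psychiatric disorders", 42, 25),
    ("Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 42, 179),
    ("Skin and subcutaneous tissue disorders", 38, 33),
    ("Vascular disorders", 33, 17),
    ("Eye disorders", 21, 12),
    ("Blood and lymphatic system disorders", 18, 30),
    ("Hepatobiliary disorders", 14, 29),
    ("Surgical and medical procedures", 11, 35),
    ("Immune system disorders", 7, 2),
    ("Ear and labyrinth disorders", 6, 5),
    ("Endocrine disorders", 6, 0),
    ("Reproductive system and breast disorders", 2, 0),
    ("Congenital, familial and genetic disorders", 2, 3),
    ("Product issues", 1, 4),
    ("Social circumstances", 1, 2),
]

# (drug, block, label, count, denominator key, printed %)
_BASELINE_ROWS = [
    ("entrectinib", "age", "<18", 32, "cohort", 5.7),
    ("entrectinib", "age", "18-64", 22, "cohort", 3.9),
    ("entrectinib", "age", ">64", 2, "cohort", 0.3),
    ("entrectinib", "age", "Unknown", 507, "cohort", 90.1),
    ("entrectinib", "sex", "Female", 286, "cohort", 50.8),
    ("entrectinib", "sex", "Male", 237, "cohort", 42.1),
    ("entrectinib", "sex", "Unknown", 40, "cohort", 7.1),
    ("entrectinib", "weight", "<80", 163, "cohort", 29.0),
    ("entrectinib", "weight", "80-100", 23, "cohort", 4.1),
    ("entrectinib", "weight", ">100", 13, "cohort", 2.3),
    ("entrectinib", "weight", "Unknown", 364, "cohort", 64.6),
    ("entrectinib", "country", "US", 278, "cohort", 49.4),
    ("entrectinib", "country", "JP", 139, "cohort", 24.7),
    ("entrectinib", "country", "DE", 14, "cohort", 2.5),
    ("entrectinib", "country", "IL", 13, "cohort", 2.3),
    ("entrectinib", "country", "FR", 12, "cohort", 2.1),
    ("entrectinib", "reporter_type", "Consumer", 180, "cohort", 32.0),
    ("entrectinib", "reporter_type", "Health professional", 369, "cohort", 65.5),
    ("entrectinib", "reporter_type", "Unknown", 14, "cohort", 2.5),
    ("entrectinib", "indication", "Non-small cell lung cancer", 167, "cohort", 29.7),
    ("entrectinib", "indication", "Lung neoplasm malignant", 107, "cohort", 19.0),
    ("entrectinib", "indication", "Neoplasm", 37, "cohort", 6.6),
    ("entrectinib", "indication", "Neoplasm malignant", 23, "cohort", 4.1),
    ("entrectinib", "indication", "Lung adenocarcinoma", 14, "cohort", 2.5),
    ("entrectinib", "serious_outcome", "OT", 229, "outcome", 44.2),
    ("entrectinib", "serious_outcome", "HO", 166, "outcome", 32.0),
    ("entrectinib", "serious_outcome", "DE", 103, "outcome", 19.9),
    ("entrectinib", "serious_outcome", "LT", 14, "outcome", 2.7),
    ("entrectinib", "serious_outcome", "DS", 6, "outcome", 1.2),
    ("larotrectinib", "age", "<18", 7, "cohort", 1.3),
    ("larotrectinib", "age", "18-64", 22, "cohort", 4.2),
    ("larotrectinib", "age", ">64", 17, "cohort", 3.3),
    ("larotrectinib", "age", "Unknown", 478, "cohort", 91.2),
    ("larotrectinib", "sex", "Female", 222, "cohort", 42.4),
    ("larotrectinib", "sex", "Male", 220, "cohort", 42.0),
    ("larotrectinib", "sex", "Unknown", 82, "cohort", 15.6),
    ("larotrectinib", "weight", "<80", 18, "cohort", 3.4),
    ("larotrectinib", "weight", "80-100", 5, "cohort", 1.0),
    ("larotrectinib", "weight", ">100", 1, "cohort", 0.2),
    ("larotrectinib", "weight", "Unknown", 500, "cohort", 95.4),
    ("larotrectinib", "country", "US", 308, "cohort", 58.8),
    ("larotrectinib", "country", "FR", 38, "cohort", 7.3),
    ("larotrectinib", "country", "MX", 25, "cohort", 4.8),
    ("larotrectinib", "country", "CA", 18, "cohort", 3.4),
    ("larotrectinib", "country", "CH", 15, "cohort", 2.9),
    ("larotrectinib", "reporter_type", "Consumer", 139, "cohort", 26.5),
    ("larotrectinib", "reporter_type", "Health professional", 384, "cohort", 73.3),
    ("larotrectinib", "reporter_type", "Unknown", 1, "cohort", 0.2),
    ("larotrectinib", "indication", "Thyroid cancer", 28, "cohort", 5.3),
    ("larotrectinib", "indication", "Neoplasm malignant", 19, "cohort", 3.6),
    ("larotrectinib", "indication", "Lung neoplasm malignant", 18, "cohort", 3.4),
    ("larotrectinib", "indication", "Neoplasm", 17, "cohort", 3.2),
    ("larotrectinib", "indication", "Sarcoma", 14, "cohort", 2.7),
    ("larotrectinib", "serious_outcome", "OT", 238, "outcome", 56.7),
    ("larotrectinib", "serious_outcome", "HO", 95, "outcome", 22.6),
    ("larotrectinib", "serious_outcome", "DE", 80, "outcome", 19.0),
    ("larotrectinib", "serious_outcome", "LT", 5, "outcome", 1.2),
    ("larotrectinib", "serious_outcome", "DS", 2, "outcome", 0.5),
]

# SOC shares quoted at two decimals; denominators are the PT totals.
_SOC_COMPOSITION_ROWS = [
    ("entrectinib", "Nervous system disorders", 304, 18.94),
    ("larotrectinib", "Nervous system disorders", 199, 14.82),
    ("entrectinib", "Cardiac disorders", 100, 6.23),
    ("larotrectinib", "Cardiac disorders", 8, 0.60),
    ("entrectinib", "Renal and urinary disorders", 90, 5.61),
    ("larotrectinib", "Renal and urinary disorders", 21, 1.56),
    ("entrectinib", "General disorders and administration site conditions", 243, 15.14),
    ("larotrectinib", "General disorders and administration site conditions", 248, 18.47),
    ("entrectinib", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 42, 2.62),
    ("larotrectinib", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 179, 13.33),
]

# onset-period shares; denominators are the TTO report counts
_TTO_PERIOD_ROWS = [
    ("entrectinib", "first month", 147, 60.5),
    ("larotrectinib", "first month", 53, 46.9),
    ("entrectinib", ">1 year", 25, 10.3),
    ("larotrectinib", ">1 year", 10, 8.9),
]

#: printed percentages that do NOT recompute from their own printed counts
#: (source typos, each off by one final digit)
KNOWN_PERCENTAGE_DISCREPANCIES = [
    ("entrectinib", "age", ">64"),               # 2/563 prints 0.3, recomputes 0.4
    ("entrectinib", "weight", "Unknown"),        # 364/563 prints 64.6, recomputes 64.7
    ("larotrectinib", "age", ">64"),             # 17/524 prints 3.3, recomputes 3.2
    ("larotrectinib", "tto_period", ">1 year"),  # 10/113 prints 8.9, recomputes 8.8
]


def soc_case_numbers() -> pd.DataFrame:
    """Per-SOC event counts per drug; columns soc, entrectinib, larotrectinib."""
    return pd.DataFrame(_SOC_ROWS, columns=["soc", "entrectinib", "larotrectinib"])


def baseline_percentages() -> pd.DataFrame:
    rows = []
    for drug, block, label, count, denom_key, printed in _BASELINE_ROWS:
        denom = COHORT_SIZES[drug] if denom_key == "cohort" else OUTCOME_ENTRY_TOTALS[drug]
        rows.append((drug, block, label, count, denom, printed, 1))
    return pd.DataFrame(rows, columns=[
        "drug", "block", "label", "count", "denominator", "printed_pct", "decimals"])


def soc_composition_percentages() -> pd.DataFrame:
    rows = [(drug, "soc_share", soc, count, PT_TOTALS[drug], printed, 2)
            for drug, soc, count, printed in _SOC_COMPOSITION_ROWS]
    return pd.DataFrame(rows, columns=[
        "drug", "block", "label", "count", "denominator", "printed_pct", "decimals"])


def tto_period_percentages() -> pd.DataFrame:
    rows = [(drug, "tto_period", label, count, TTO_REPORT_COUNTS[drug], printed, 1)
            for drug, label, count, printed in _TTO_PERIOD_ROWS]
    return pd.DataFrame(rows, columns=[
        "drug", "block", "label", "count", "denominator", "printed_pct", "decimals"])


def all_printed_percentages() -> pd.DataFrame:
    return pd.concat(
        [baseline_percentages(), soc_composition_percentages(), tto_period_percentages()],
        ignore_index=True)


def consistency_report() -> pd.DataFrame:
    """Recompute every printed percentage from its printed count.

    Returns the full table with ``recomputed_pct`` and ``consistent``
    columns; the rows expected to fail are exactly
    :data:`KNOWN_PERCENTAGE_DISCREPANCIES`.
    """
    return check_percentages(all_printed_percentages())
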