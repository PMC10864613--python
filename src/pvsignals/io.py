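"""Reading FAERS-dialect quarterly ASCII tables and assembling case-centric records.

FAERS distributes each quarter as a set of "$"-delimited ASCII tables keyed by
``PRIMARYID`` (one safety-report *version*) and ``CASEID`` (one underlying
case, possibly re-submitted across quarters).  This module parses that dialect,
keeps malformed dates as raw strings with a validity flag (exclusion decisions
belong to downstream stages, not the parser), and joins the child tables into
case-centric records.

Two representations are provided:

* :class:`CaseSet` — a column-oriented container (one DataFrame per table)
  used by the pipeline; all heavy operations are vectorised on it.
* :class:`CaseReport` — a per-case record with nested drug/reaction/therapy
  entries, materialised on demand via :meth:`CaseSet.reports` for inspection
  and small-data tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

DEMO_COLUMNS = [
    "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
    "SEX", "WT", "REPORTER_COUNTRY", "OCCP_COD",
]
DRUG_COLUMNS = ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"]
REAC_COLUMNS = ["PRIMARYID", "PT"]
THER_COLUMNS = ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT", "END_DT"]
INDI_COLUMNS = ["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"]
OUTC_COLUMNS = ["PRIMARYID", "OUTC_COD"]

TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "ther": THER_COLUMNS,
    "indi": INDI_COLUMNS,
    "outc": OUTC_COLUMNS,
}

TABLE_NAMES = tuple(TABLE_COLUMNS)

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Occupation codes mapped onto the two reporter categories used in baseline
#: tables; anything else (or blank) is treated as unknown.
REPORTER_TYPE_MAP = {
    "MD": "health professional",
    "PH": "health professional",
    "RN": "health professional",
    "OT": "health professional",
    "HP": "health professional",
    "CN": "consumer",
    "LW": "consumer",
}

_FULL_DATE_RE = re.compile(r"^\d{8}$")
_PARTIAL_DATE_RE = re.compile(r"^\d{6}$|^\d{4}$")


class FormatError(ValueError):
    """A quarterly file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Date handling
# ---------------------------------------------------------------------------

def date_validity(value: str | None) -> str:
    """Classify a raw FAERS date string.

    Returns one of ``"full"`` (valid ``YYYYMMDD``), ``"partial"``
    (``YYYYMM`` or ``YYYY``), ``"missing"`` (blank) or ``"invalid"``.
    """
    if value is None:
        return "missing"
    s = str(value).strip()
    if not s:
        return "missing"
    if _FULL_DATE_RE.match(s):
        ts = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
        return "full" if ts is not pd.NaT else "invalid"
    if _PARTIAL_DATE_RE.match(s):
        return "partial"
    return "invalid"


def date_validity_series(values: pd.Series) -> pd.Series:
    """Vectorised :func:`date_validity`."""
    s = values.fillna("").astype(str).str.strip()
    out = pd.Series("invalid", index=s.index, dtype=object)
    out[s == ""] = "missing"
    partial = s.str.fullmatch(r"\d{6}|\d{4}")
    out[partial.fillna(False)] = "partial"
    full = s.str.fullmatch(r"\d{8}")
    full_ok = full.fillna(False) & pd.to_datetime(
        s.where(full.fillna(False), None), format="%Y%m%d", errors="coerce"
    ).notna()
    out[full_ok] = "full"
    return out


def parse_full_dates(values: pd.Series) -> pd.Series:
    """Parse ``YYYYMMDD`` strings to datetimes; anything else becomes NaT."""
    s = values.fillna("").astype(str).str.strip()
    s = s.where(s.str.fullmatch(r"\d{8}").fillna(False), None)
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def quarter_of_date(values: pd.Series) -> pd.Series:
    """Quarter label (``2021Q3`` style) of ``YYYYMMDD`` strings; blank if unparsable."""
    dt = parse_full_dates(values)
    labels = dt.dt.year.astype("Int64").astype(str) + "Q" + dt.dt.quarter.astype("Int64").astype(str)
    return labels.where(dt.notna(), "")


_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


def quarter_sort_key(label: str) -> int:
    m = _QUARTER_RE.match(label)
    if not m:
        raise ValueError(f"not a quarter label: {label!r}")
    return int(m.group(1)) * 4 + int(m.group(2)) - 1


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels from *start* to *end*."""
    lo, hi = quarter_sort_key(start), quarter_sort_key(end)
    if lo > hi:
        raise ValueError(f"empty quarter range {start}..{end}")
    return [f"{k // 4}Q{k % 4 + 1}" for k in range(lo, hi + 1)]


# ---------------------------------------------------------------------------
# Demographic normalisation
# ---------------------------------------------------------------------------

#: AGE_COD multipliers to years.  DEC is "decade" in FAERS; unknown codes → NaN.
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12, "WK": 1.0 / 52, "DY": 1.0 / 365, "HR": 1.0 / 8760}


def age_in_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    value = pd.to_numeric(age, errors="coerce")
    mult = age_cod.fillna("").astype(str).str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    return value * mult


def weight_in_kg(wt: pd.Series) -> pd.Series:
    """FAERS weights are assumed to be kilograms already."""
    return pd.to_numeric(wt, errors="coerce")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TableBundle:
    """The six quarterly tables, as raw string DataFrames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    @classmethod
    def empty(cls) -> "TableBundle":
        return cls(**{
            name: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for name, cols in TABLE_COLUMNS.items()
        })

    def equals(self, other: "TableBundle") -> bool:
        for name in TABLE_NAMES:
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if not a.fillna("").astype(str).equals(b.fillna("").astype(str)):
                return False
        return True


@dataclass
class DrugEntry:
    drug_seq: int
    role_code: str
    drugname: str
    prod_ai: str | None = None


@dataclass
class TherapyEntry:
    dsg_drug_seq: int
    start_dt: str | None = None
    end_dt: str | None = None


@dataclass
class CaseReport:
    """One safety-report version with its nested child records."""

    primaryid: str
    caseid: str
    fda_dt: str | None = None
    event_dt: str | None = None
    age_value: float | None = None
    age_unit: str | None = None
    sex: str | None = None
    weight_kg: float | None = None
    reporter_country: str | None = None
    reporter_type: str | None = None
    outcomes: frozenset = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    therapies: list[TherapyEntry] = field(default_factory=list)
    indications: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class CaseSet:
    """Column-oriented view of assembled cases (one demo row per PRIMARYID)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    orphan_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def primaryids(self) -> pd.Series:
        return self.demo["PRIMARYID"]

    def filter_primaryids(self, keep: Iterable[str]) -> "CaseSet":
        keep = set(keep)
        out = {}
        for name in TABLE_NAMES:
            df = getattr(self, name)
            out[name] = df[df["PRIMARYID"].isin(keep)].reset_index(drop=True)
        return CaseSet(**out, orphan_counts=dict(self.orphan_counts))

    def filter_window(self, quarters: Sequence[str]) -> "CaseSet":
        """Restrict to cases whose FDA_DT falls inside the given quarters."""
        q = quarter_of_date(self.demo["FDA_DT"])
        keep = self.demo.loc[q.isin(set(quarters)), "PRIMARYID"]
        return self.filter_primaryids(keep)

    def reports(self) -> list[CaseReport]:
        """Materialise nested :class:`CaseReport` objects (small data only)."""
        drugs = _group_lists(self.drug, lambda r: DrugEntry(
            int(r.DRUG_SEQ), str(r.ROLE_COD), str(r.DRUGNAME),
            r.PROD_AI if r.PROD_AI not in ("", None) else None))
        reacs = _group_lists(self.reac, lambda r: str(r.PT))
        thers = _group_lists(self.ther, lambda r: TherapyEntry(
            int(r.DSG_DRUG_SEQ),
            r.START_DT if r.START_DT not in ("", None) else None,
            r.END_DT if r.END_DT not in ("", None) else None))
        indis = _group_lists(self.indi, lambda r: (int(r.INDI_DRUG_SEQ), str(r.INDI_PT)))
        outcs = _group_lists(self.outc, lambda r: str(r.OUTC_COD))

        ages = age_in_years(self.demo["AGE"], self.demo["AGE_COD"])
        weights = weight_in_kg(self.demo["WT"])
        out = []
        for i, row in enumerate(self.demo.itertuples(index=False)):
            pid = str(row.PRIMARYID)
            occp = str(row.OCCP_COD or "").strip().upper()
            out.append(CaseReport(
                primaryid=pid,
                caseid=str(row.CASEID),
                fda_dt=row.FDA_DT or None,
                event_dt=row.EVENT_DT or None,
                age_value=None if pd.isna(ages.iloc[i]) else float(ages.iloc[i]),
                age_unit=(row.AGE_COD or None),
                sex=row.SEX if row.SEX in ("F", "M") else None,
                weight_kg=None if pd.isna(weights.iloc[i]) else float(weights.iloc[i]),
                reporter_country=row.REPORTER_COUNTRY or None,
                reporter_type=REPORTER_TYPE_MAP.get(occp),
                outcomes=frozenset(outcs.get(pid, [])),
                drugs=drugs.get(pid, []),
                reactions=reacs.get(pid, []),
                therapies=thers.get(pid, []),
                indications=indis.get(pid, []),
            ))
        return out


def _group_lists(df: pd.DataFrame, make) -> dict[str, list]:
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.PRIMARYID), []).append(make(row))
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one "$"-delimited quarterly file, validating mandatory columns."""
    path = Path(path)
    expected = TABLE_COLUMNS[table]
    try:
        df = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False,
                         na_values=[], engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("empty file %s; returning empty %s table", path, table)
        return pd.DataFrame({c: pd.Series(dtype=object) for c in expected})
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing} for {table.upper()}")
    return df[expected]


def read_quarter(paths: Mapping[str, str | Path]) -> TableBundle:
    """Read one quarter's tables.

    *paths* maps table name (``demo`` … ``outc``) to a file path.  Missing
    child tables default to empty; a missing DEMO is an error since cases
    cannot exist without it.
    """
    if "demo" not in paths:
        raise FormatError("a quarter requires at least a DEMO file")
    tables = {}
    for name in TABLE_NAMES:
        if name in paths:
            tables[name] = read_table(paths[name], name)
        else:
            tables[name] = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    return TableBundle(**tables)


def read_quarter_dir(directory: str | Path, quarter: str) -> TableBundle:
    """Read ``DEMO<quarter>.txt`` … ``OUTC<quarter>.txt`` from *directory*."""
    directory = Path(directory)
    paths = {}
    for name in TABLE_NAMES:
        p = directory / f"{name.upper()}{quarter}.txt"
        if p.exists():
            paths[name] = p
    return read_quarter(paths)


def assemble_cases(
    bundles: Mapping[str, TableBundle],
    window: Sequence[str] | None = None,
) -> CaseSet:
    """Assemble quarterly bundles into a :class:`CaseSet`.

    *bundles* maps quarter label → bundle.  If *window* is given, quarters
    outside it are dropped before assembly.  Child rows whose PRIMARYID has
    no DEMO row are orphans: counted, logged and dropped, never fatal.
    """
    if window is not None:
        allowed = set(window)
        bundles = {q: b for q, b in bundles.items() if q in allowed}

    parts: dict[str, list[pd.DataFrame]] = {name: [] for name in TABLE_NAMES}
    for quarter in sorted(bundles, key=quarter_sort_key):
        b = bundles[quarter]
        demo = b.demo.copy()
        demo["QUARTER"] = quarter
        parts["demo"].append(demo)
        for name in TABLE_NAMES[1:]:
            parts[name].append(getattr(b, name))

    def _concat(name: str) -> pd.DataFrame:
        cols = TABLE_COLUMNS[name] + (["QUARTER"] if name == "demo" else [])
        if not parts[name]:
            return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        return pd.concat(parts[name], ignore_index=True)

    demo = _concat("demo")
    known = set(demo["PRIMARYID"])
    orphans: dict[str, int] = {}
    tables = {"demo": demo}
    for name in TABLE_NAMES[1:]:
        df = _concat(name)
        mask = df["PRIMARYID"].isin(known)
        n_orphan = int((~mask).sum())
        if n_orphan:
            logger.warning("%d orphan %s row(s) without DEMO parent dropped", n_orphan, name.upper())
        orphans[name] = n_orphan
        tables[name] = df[mask].reset_index(drop=True)
    return CaseSet(**tables, orphan_counts=orphans)
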