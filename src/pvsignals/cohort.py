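"""Target-drug cohort construction and event-level expansion.

The cohort is restricted to reports naming the target drug as *primary
suspect* (role code PS); naming it as secondary suspect, concomitant or
interacting is not enough.  Drug recognition goes through a small dictionary
of generic and brand names, matched case-insensitively after trimming —
either against the whole string (default) or as a word-boundary substring so
that salt forms like "LAROTRECTINIB MESYLATE" can be captured when wanted.

The counting unit downstream is the *event*: one record per distinct
preferred term (PT) per case, mapped to its primary System Organ Class
(SOC).  Repeated identical PTs within one report count once.  Terms that
match the drug's indications can be excluded so that disease symptoms are
not mistaken for drug reactions.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import CaseSet, DrugEntry

logger = logging.getLogger(__name__)

__all__ = [
    "DrugDictionary",
    "match_drug",
    "match_drug_frame",
    "select_primary_suspect",
    "explode_events",
    "exclude_indication_terms",
    "load_pt_soc_map",
    "Cohort",
]

UNMAPPED_SOC = "UNMAPPED"


class DrugDictionary(BaseModel):
    """Names under which one target drug appears in DRUGNAME / PROD_AI."""

    generic: str
    brands: list[str] = Field(default_factory=list)
    active_ingredients: list[str] = Field(default_factory=list)
    mode: Literal["whole", "substring"] = "whole"

    @field_validator("generic")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("generic name must be non-empty")
        return v

    def names(self) -> list[str]:
        return [n.strip().lower() for n in
                [self.generic, *self.brands, *self.active_ingredients] if n.strip()]


def _norm(s: str | None) -> str:
    return (s or "").strip().lower()


def match_drug(entry: DrugEntry, dictionary: DrugDictionary) -> bool:
    """True iff the entry's DRUGNAME or PROD_AI matches a dictionary name."""
    names = dictionary.names()
    fields = [_norm(entry.drugname), _norm(entry.prod_ai)]
    if dictionary.mode == "whole":
        return any(f in names for f in fields if f)
    pattern = re.compile(r"\b(?:" + "|".join(map(re.escape, names)) + r")\b")
    return any(pattern.search(f) for f in fields if f)


def match_drug_frame(drug: pd.DataFrame, dictionary: DrugDictionary) -> pd.Series:
    """Vectorised :func:`match_drug` over a DRUG table."""
    names = dictionary.names()
    dn = drug["DRUGNAME"].fillna("").astype(str).str.strip().str.lower()
    ai = drug["PROD_AI"].fillna("").astype(str).str.strip().str.lower()
    if dictionary.mode == "whole":
        nameset = set(names)
        return dn.isin(nameset) | ai.isin(nameset)
    pattern = r"\b(?:" + "|".join(map(re.escape, names)) + r")\b"
    return dn.str.contains(pattern, regex=True) | ai.str.contains(pattern, regex=True)


class Cohort:
    """A PS-restricted target-drug cohort with its matched drug sequences."""

    def __init__(self, cases: CaseSet, matched_drug_seq: pd.DataFrame):
        #: deduplicated cases with the target drug as primary suspect
        self.cases = cases
        #: columns PRIMARYID, DRUG_SEQ — the PS entries that matched the dictionary
        self.matched_drug_seq = matched_drug_seq

    @property
    def n_cases(self) -> int:
        return self.cases.n_cases


def select_primary_suspect(cases: CaseSet, dictionary: DrugDictionary) -> Cohort:
    """Cases containing >=1 matched drug entry with role code PS."""
    drug = cases.drug
    matched = match_drug_frame(drug, dictionary)
    role_ps = drug["ROLE_COD"].fillna("").astype(str).str.strip().str.upper() == "PS"
    hits = drug.loc[matched & role_ps, ["PRIMARYID", "DRUG_SEQ"]].drop_duplicates()
    cohort_cases = cases.filter_primaryids(hits["PRIMARYID"])
    return Cohort(cohort_cases, hits.reset_index(drop=True))


def load_pt_soc_map(path) -> pd.Series:
    """Two-column delimited file (pt, soc) → Series indexed by lower-cased PT."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    pt_col, soc_col = df.columns[:2]
    return pd.Series(df[soc_col].to_numpy(),
                     index=df[pt_col].astype(str).str.strip().str.lower())


def explode_events(cases: CaseSet, pt_to_soc: pd.Series | dict) -> pd.DataFrame:
    """One event per distinct PT per case, with its SOC attached.

    Returns a DataFrame with columns ``PRIMARYID``, ``pt`` (as reported),
    ``soc``.  PTs absent from the mapping get soc ``"UNMAPPED"`` and are
    counted in the log.  PT lookup is case-insensitive.
    """
    if not isinstance(pt_to_soc, pd.Series):
        pt_to_soc = pd.Series(pt_to_soc)
    pt_to_soc = pd.Series(pt_to_soc.to_numpy(),
                          index=pt_to_soc.index.astype(str).str.strip().str.lower())

    reac = cases.reac
    events = pd.DataFrame({
        "PRIMARYID": reac["PRIMARYID"].astype(str),
        "pt": reac["PT"].fillna("").astype(str).str.strip(),
    })
    events = events[events["pt"] != ""]
    events = events.assign(_ptl=events["pt"].str.lower())
    events = events.drop_duplicates(subset=["PRIMARYID", "_ptl"])
    events["soc"] = events["_ptl"].map(pt_to_soc).fillna(UNMAPPED_SOC)
    n_unmapped = int((events["soc"] == UNMAPPED_SOC).sum())
    if n_unmapped:
        logger.warning("%d event(s) with PT missing from the SOC mapping", n_unmapped)
    return events.drop(columns="_ptl").reset_index(drop=True)


def exclude_indication_terms(events: pd.DataFrame, indication_pts: Iterable[str]) -> pd.DataFrame:
    """Drop events whose PT is an indication term (exact match, case-folded)."""
    terms = {str(t).strip().lower() for t in indication_pts}
    if not terms:
        return events.reset_index(drop=True)
    mask = events["pt"].str.lower().isin(terms)
    n_removed = int(mask.sum())
    if n_removed:
        logger.info("excluded %d indication-related event(s)", n_removed)
    out = events[~mask].reset_index(drop=True)
    if out.empty and len(events):
        logger.warning("all events were indication-related; empty event set")
    return out


def observed_indication_terms(cohort: Cohort) -> set[str]:
    """Default indication list: INDI_PT values observed for the target drug."""
    indi = cohort.cases.indi
    matched = cohort.matched_drug_seq
    keyed = indi.merge(matched, left_on=["PRIMARYID", "INDI_DRUG_SEQ"],
                       right_on=["PRIMARYID", "DRUG_SEQ"], how="inner")
    return {t for t in keyed["INDI_PT"].fillna("").astype(str).str.strip() if t}
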