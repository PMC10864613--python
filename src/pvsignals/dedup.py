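"""FDA-recommended deduplication of re-submitted safety reports.

A case (CASEID) may be re-submitted across quarterly extracts under new
report versions (PRIMARYIDs).  Before any counting, exactly one version per
case is kept: the one with the most recent FDA_DT, and on FDA_DT ties the
higher PRIMARYID.  A missing FDA_DT loses to any present date ("most recent"
cannot select an unknown date); two missing dates fall through to the
PRIMARYID rule.  PRIMARYIDs are compared numerically when both parse as
integers, lexicographically otherwise.

The kept set is a pure function of the input *set* — input order never
matters — and the operation is idempotent.
"""

from __future__ import annotations

import pandas as pd

from .io import CaseSet

__all__ = ["deduplicate"]


def _fda_key(fda_dt: pd.Series) -> pd.Series:
    """Sortable FDA_DT key; missing/invalid dates order before any real date."""
    key = pd.to_numeric(fda_dt.fillna("").astype(str).str.strip(), errors="coerce")
    return key.fillna(-1)


def _primaryid_key(primaryid: pd.Series) -> pd.Series:
    """Numeric when all ids parse as integers, else lexicographic."""
    s = primaryid.fillna("").astype(str)
    num = pd.to_numeric(s, errors="coerce")
    if num.notna().all():
        return num
    return s


def deduplicate(cases: CaseSet) -> tuple[CaseSet, pd.DataFrame]:
    """Keep one report version per CASEID.

    Returns the deduplicated :class:`~pvsignals.io.CaseSet` and an audit
    table with one row per *removed* version: columns ``caseid``,
    ``removed_primaryid``, ``kept_primaryid``.
    """
    demo = cases.demo
    if demo.empty:
        return cases, pd.DataFrame(columns=["caseid", "removed_primaryid", "kept_primaryid"])

    ranked = demo.assign(
        _fda=_fda_key(demo["FDA_DT"]),
        _pid=_primaryid_key(demo["PRIMARYID"]),
    ).sort_values(["CASEID", "_fda", "_pid"], kind="mergesort")
    kept = ranked.groupby("CASEID", sort=False).tail(1)
    winners = dict(zip(kept["CASEID"], kept["PRIMARYID"]))

    removed = ranked[~ranked["PRIMARYID"].isin(set(kept["PRIMARYID"]))]
    audit = pd.DataFrame({
        "caseid": removed["CASEID"].to_numpy(),
        "removed_primaryid": removed["PRIMARYID"].to_numpy(),
        "kept_primaryid": removed["CASEID"].map(winners).to_numpy(),
    }).sort_values(["caseid", "removed_primaryid"]).reset_index(drop=True)

    return cases.filter_primaryids(kept["PRIMARYID"]), audit
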