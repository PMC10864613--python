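"""Synthetic FAERS-like quarterly data with known ground truth.

Spontaneous-report databases cannot be redistributed alongside a package, and
real extracts carry no ground truth, so every downstream stage here is
exercised on simulated quarterly report streams that reproduce the structural
quirks the pipeline must survive: duplicate CASEIDs re-submitted with later
FDA_DTs (and occasional FDA_DT ties resolved by PRIMARYID), role-coded drug
entries, several preferred terms (PTs) per case, partial ``YYYYMM`` dates,
Table-2-like demographic missingness, and Weibull-distributed onset
intervals.

The generator plants drug–event associations of configurable strength: for a
PT with rate ratio λ, reaction slots of target-drug cases draw that PT with
probability proportional to ``background_rate × λ`` while all other cases use
the background rate alone.  The planted λ is therefore the (approximate)
event-level reporting-rate ratio the disproportionality stage should recover,
up to the renormalisation of the target-case PT distribution.

Everything is driven by one :class:`SyntheticScenario`; a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io import (
    DELIMITER,
    TABLE_COLUMNS,
    TABLE_NAMES,
    TableBundle,
    quarter_of_date,
    quarter_range,
    quarter_sort_key,
)

__all__ = [
    "Missingness",
    "TTODistribution",
    "SyntheticScenario",
    "SyntheticData",
    "generate",
    "write_quarterly_ascii",
    "read_ground_truth",
]


class ScenarioError(ValueError):
    """The scenario violates a generator precondition."""


class Missingness(BaseModel):
    """Per-field probabilities that a generated value is blanked out."""

    age: float = Field(0.90, ge=0, le=1)
    sex: float = Field(0.10, ge=0, le=1)
    weight: float = Field(0.80, ge=0, le=1)
    event_dt: float = Field(0.35, ge=0, le=1)
    start_dt: float = Field(0.35, ge=0, le=1)
    country: float = Field(0.02, ge=0, le=1)
    occupation: float = Field(0.02, ge=0, le=1)


class TTODistribution(BaseModel):
    """True Weibull time-to-onset law, in days."""

    shape: float = Field(0.56, gt=0)
    scale: float = Field(30.0, gt=0)


_DEFAULT_NAMED_PTS = [
    "Dizziness", "Renal impairment", "Taste disorder", "Ataxia", "Oedema",
    "Peripheral neuropathy", "Paraesthesia", "Fatigue", "Nausea", "Headache",
    "Vomiting", "Diarrhoea", "Constipation", "Weight increased", "Anaemia",
    "Pyrexia", "Rash", "Dyspnoea", "Ascites", "Disease progression",
]

_DEFAULT_OTHER_DRUGS = [
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
    "LEVOTHYROXINE", "AMLODIPINE", "METOPROLOL", "ALBUTEROL", "GABAPENTIN",
    "HYDROCHLOROTHIAZIDE", "SERTRALINE", "IBUPROFEN", "PREDNISONE",
    "PEMBROLIZUMAB", "CARBOPLATIN", "PACLITAXEL", "OSIMERTINIB",
    "CRIZOTINIB", "WARFARIN", "FUROSEMIDE", "PANTOPRAZOLE", "TRAMADOL",
    "DULOXETINE", "INSULIN GLARGINE", "RIVAROXABAN", "APIXABAN",
    "CLOPIDOGREL", "TAMSULOSIN", "ROSUVASTATIN",
]

_INDICATION_TERMS = [
    "Non-small cell lung cancer", "Thyroid cancer", "Neoplasm malignant",
    "Lung neoplasm malignant", "Sarcoma", "Neoplasm", "Lung adenocarcinoma",
    "Colorectal cancer", "Breast cancer", "Hypertension", "Type 2 diabetes mellitus",
]

_COUNTRIES = ["US", "JP", "DE", "FR", "MX", "CA", "CH", "IL", "GB", "IT"]
_COUNTRY_W = [0.50, 0.12, 0.06, 0.07, 0.05, 0.05, 0.04, 0.03, 0.05, 0.03]
_OCCP = ["MD", "PH", "OT", "CN", "RN"]
_OCCP_W = [0.30, 0.12, 0.18, 0.30, 0.10]
_OUTC = ["OT", "HO", "DE", "LT", "DS", "CA", "RI"]
_OUTC_W = [0.40, 0.28, 0.17, 0.05, 0.03, 0.02, 0.05]


def _default_pt_vocabulary(n_pts: int = 130, n_socs: int = 26) -> dict[str, str]:
    """PT → synthetic SOC map; 26 organ classes mirror real SOC granularity."""
    pts = list(_DEFAULT_NAMED_PTS) + [f"Reaction term {i:03d}" for i in range(n_pts - len(_DEFAULT_NAMED_PTS))]
    return {pt: f"SOC{(i % n_socs) + 1:02d}" for i, pt in enumerate(pts)}


#: background-rate ranks forced onto the default planted terms.  Planting
#: multiplies a term's slot weight by its rate ratio, which renormalises the
#: whole target-case PT distribution; keeping planted terms on modest
#: background rates keeps that attenuation small (~10%), so the realised
#: reporting-rate ratio stays close to the nominal lambda.
_PLANTED_RANKS = {
    "Dizziness": 40,
    "Renal impairment": 50,
    "Taste disorder": 60,
    "Ataxia": 70,
    "Oedema": 80,
}


def _default_background_rates(pts: list[str]) -> dict[str, float]:
    """Zipf-like marginal PT rates normalised to a proper categorical.

    Default planted terms are pinned to mid-tail ranks (see
    :data:`_PLANTED_RANKS`) by swapping rank positions.
    """
    rank = {pt: i for i, pt in enumerate(pts)}
    for pt, target in _PLANTED_RANKS.items():
        if pt not in rank or target >= len(pts):
            continue
        holder = next(p for p, r in rank.items() if r == target)
        rank[holder], rank[pt] = rank[pt], target
    raw = np.array([1.0 / (rank[pt] + 10) for pt in pts])
    raw /= raw.sum()
    return dict(zip(pts, raw))


class SyntheticScenario(BaseModel):
    """Parameters of one simulated reporting stream.

    Defaults emulate a first-generation NTRK-inhibitor cohort embedded in a
    desk-scale background: ~1.1% of reports name the target drug as primary
    suspect, cases list a truncated-geometric number of PTs (mean ≈ 2.6),
    onsets follow Weibull(shape 0.56, scale 30 d) so the median sits near
    16 days, and demographic fields are blanked at rates typical of oncology
    spontaneous reports (age unknown ≈ 90%).
    """

    n_reports: int = Field(50_000, gt=0)
    quarters: list[str] = Field(default_factory=lambda: quarter_range("2019Q3", "2023Q1"))
    target_generic: str = "entrectinib"
    target_brand: str = "ROZLYTREK"
    other_drugs: list[str] = Field(default_factory=lambda: list(_DEFAULT_OTHER_DRUGS))
    pt_vocabulary: dict[str, str] = Field(default_factory=_default_pt_vocabulary)
    background_rates: dict[str, float] = Field(default_factory=dict)
    signal_spec: dict[str, float] = Field(
        default_factory=lambda: {
            "Dizziness": 8.0,
            "Renal impairment": 6.0,
            "Taste disorder": 4.0,
            "Ataxia": 4.0,
            "Oedema": 2.0,
        }
    )
    target_share: float = Field(0.011, gt=0, lt=1)
    pt_per_case_p: float = Field(0.39, gt=0, lt=1)
    max_pts_per_case: int = Field(10, ge=1)
    duplication_rate: float = Field(0.08, ge=0, lt=1)
    fda_dt_tie_fraction: float = Field(0.15, ge=0, le=1)
    partial_date_fraction: float = Field(0.05, ge=0, le=1)
    missingness: Missingness = Field(default_factory=Missingness)
    tto_distribution: TTODistribution = Field(default_factory=TTODistribution)
    indication_rate: float = Field(0.6, ge=0, le=1)
    target_as_concomitant_rate: float = Field(0.004, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticScenario":
        if not self.pt_vocabulary:
            raise ScenarioError("pt_vocabulary must be non-empty")
        if not self.other_drugs:
            raise ScenarioError("drug vocabulary needs at least one background drug")
        if not self.background_rates:
            object.__setattr__(self, "background_rates",
                               _default_background_rates(list(self.pt_vocabulary)))
        unknown = set(self.background_rates) - set(self.pt_vocabulary)
        if unknown:
            raise ScenarioError(f"background rate for PT(s) outside the vocabulary: {sorted(unknown)[:3]}")
        total = sum(self.background_rates.values())
        if total > 1 + 1e-9:
            raise ScenarioError(f"background rates sum to {total:.3f} > 1 per event slot")
        if any(r <= 0 for r in self.background_rates.values()):
            raise ScenarioError("background rates must be positive")
        for pt, lam in self.signal_spec.items():
            if pt not in self.pt_vocabulary:
                raise ScenarioError(f"signal PT {pt!r} not in vocabulary")
            if lam < 1:
                raise ScenarioError(f"signal rate ratio must be >= 1, got {lam} for {pt!r}")
        for q in self.quarters:
            quarter_range(q, q)  # validates label format
        return self

    # -- derived quantities -------------------------------------------------

    def true_rate_ratio(self, pt: str) -> float:
        return self.signal_spec.get(pt, 1.0)

    def _pt_weights(self, target: bool) -> tuple[list[str], np.ndarray]:
        pts = list(self.pt_vocabulary)
        w = np.array([self.background_rates[pt] for pt in pts])
        if target:
            w = w * np.array([self.true_rate_ratio(pt) for pt in pts])
        return pts, w / w.sum()

    def mean_pts_per_case(self) -> float:
        k = np.arange(1, self.max_pts_per_case + 1)
        p = self.pt_per_case_p * (1 - self.pt_per_case_p) ** (k - 1)
        p /= p.sum()
        return float((k * p).sum())

    def expected_signal_case_count(self, pt: str) -> float:
        """Expected number of target-drug cases reporting *pt* (distinct-per-case)."""
        pts, w = self._pt_weights(target=True)
        w_pt = w[pts.index(pt)]
        k = np.arange(1, self.max_pts_per_case + 1)
        pk = self.pt_per_case_p * (1 - self.pt_per_case_p) ** (k - 1)
        pk /= pk.sum()
        p_case = float((pk * (1 - (1 - w_pt) ** k)).sum())
        return self.n_reports * self.target_share * p_case


@dataclass
class SyntheticData:
    """Generated quarterly bundles plus the ground-truth ledger."""

    scenario: SyntheticScenario
    bundles: dict[str, TableBundle]
    ground_truth: pd.DataFrame     # columns: pt, soc, true_lambda, is_signal
    duplicates: pd.DataFrame       # columns: caseid, original_primaryid, duplicate_primaryid

    def combined(self) -> TableBundle:
        """All quarters concatenated into one bundle."""
        tables = {}
        for name in TABLE_NAMES:
            frames = [getattr(b, name) for b in self.bundles.values()]
            tables[name] = (pd.concat(frames, ignore_index=True) if frames
                            else TableBundle.empty().tables()[name])
        return TableBundle(**tables)


def _truncated_geometric(rng: np.random.Generator, p: float, kmax: int, n: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    w = p * (1 - p) ** (k - 1)
    w /= w.sum()
    return rng.choice(k, size=n, p=w)


def _fmt_dates(days: np.ndarray, origin: pd.Timestamp) -> np.ndarray:
    dt = origin + pd.to_timedelta(days, unit="D")
    return dt.strftime("%Y%m%d").to_numpy(dtype=object)


def generate(scenario: SyntheticScenario) -> SyntheticData:
    """Generate quarterly FAERS-dialect tables for *scenario*.

    Deterministic for a fixed ``scenario.seed``.  The returned ground-truth
    ledger records every PT's true rate ratio and the duplicate-submission
    pairs, so tests can score signal recovery and dedup behaviour exactly.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n = sc.n_reports

    quarters = sorted(sc.quarters, key=quarter_sort_key)
    origin = pd.Period(quarters[0], freq="Q").start_time
    window_end = pd.Period(quarters[-1], freq="Q").end_time.normalize()
    horizon = (window_end - origin).days

    caseids = (10_000_000 + np.arange(n)).astype(str)
    primaryids = np.char.add(caseids, "1")

    fda_days = rng.integers(0, horizon + 1, n)
    delay = rng.integers(0, 61, n)
    tto = np.round(rng.weibull(sc.tto_distribution.shape, n) * sc.tto_distribution.scale).astype(int)
    event_days = fda_days - delay
    start_days = event_days - tto

    fda_dt = _fmt_dates(fda_days, origin)
    event_dt = _fmt_dates(event_days, origin)
    start_dt = _fmt_dates(start_days, origin)
    ther_end = _fmt_dates(np.minimum(event_days + rng.integers(0, 120, n), fda_days), origin)

    # --- drugs -------------------------------------------------------------
    is_target = rng.random(n) < sc.target_share
    n_t = int(is_target.sum())
    target_names = rng.choice(
        [sc.target_generic.upper(), sc.target_brand.upper(), sc.target_generic.capitalize()], n_t)
    other_idx = rng.integers(0, len(sc.other_drugs), n)
    drugname = np.array(sc.other_drugs, dtype=object)[other_idx]
    drugname[is_target] = target_names
    prod_ai = np.where(is_target, sc.target_generic.upper(), drugname).astype(object)
    prod_ai[rng.random(n) < 0.2] = ""

    drug_rows = [pd.DataFrame({
        "PRIMARYID": primaryids, "DRUG_SEQ": "1", "ROLE_COD": "PS",
        "DRUGNAME": drugname, "PROD_AI": prod_ai,
    })]
    # concomitant background drugs (role C/SS) for realism
    n_con = rng.integers(0, 3, n)
    con_pid = np.repeat(primaryids, n_con)
    con_total = int(n_con.sum())
    con_name = np.array(sc.other_drugs, dtype=object)[rng.integers(0, len(sc.other_drugs), con_total)]
    # a small fraction of non-target cases carry the target drug in a
    # non-suspect role: they must stay out of the PS cohort
    con_is_target = rng.random(con_total) < sc.target_as_concomitant_rate
    con_name[con_is_target] = sc.target_brand.upper()
    con_seq = np.concatenate([np.arange(2, 2 + k) for k in n_con]) if con_total else np.array([], dtype=int)
    con_role = rng.choice(["C", "SS", "I"], con_total, p=[0.8, 0.15, 0.05])
    drug_rows.append(pd.DataFrame({
        "PRIMARYID": con_pid, "DRUG_SEQ": con_seq.astype(str), "ROLE_COD": con_role,
        "DRUGNAME": con_name, "PROD_AI": con_name,
    }))
    drug = pd.concat(drug_rows, ignore_index=True)

    # --- reactions ---------------------------------------------------------
    k_pts = _truncated_geometric(rng, sc.pt_per_case_p, sc.max_pts_per_case, n)
    reac_pid = np.repeat(primaryids, k_pts)
    reac_target = np.repeat(is_target, k_pts)
    total_slots = int(k_pts.sum())
    pts_bg, w_bg = sc._pt_weights(target=False)
    pts_t, w_t = sc._pt_weights(target=True)
    pt_col = np.empty(total_slots, dtype=object)
    n_slots_t = int(reac_target.sum())
    pt_col[reac_target] = rng.choice(pts_t, n_slots_t, p=w_t)
    pt_col[~reac_target] = rng.choice(pts_bg, total_slots - n_slots_t, p=w_bg)
    reac = pd.DataFrame({"PRIMARYID": reac_pid, "PT": pt_col})

    # --- therapy (PS drug only) -------------------------------------------
    start_out = start_dt.copy()
    miss = rng.random(n) < sc.missingness.start_dt
    start_out[miss] = ""
    part = (~miss) & (rng.random(n) < sc.partial_date_fraction)
    start_out[part] = np.array([s[:6] for s in start_out[part]], dtype=object)
    end_out = ther_end.copy()
    end_out[rng.random(n) < 0.5] = ""
    ther = pd.DataFrame({
        "PRIMARYID": primaryids, "DSG_DRUG_SEQ": "1",
        "START_DT": start_out, "END_DT": end_out,
    })

    # --- indications -------------------------------------------------------
    has_indi = rng.random(n) < sc.indication_rate
    ind_pid = primaryids[has_indi]
    n_ind = len(ind_pid)
    target_ind = rng.choice(_INDICATION_TERMS[:7], n_ind)
    other_ind = rng.choice(_INDICATION_TERMS, n_ind)
    ind_pt = np.where(is_target[has_indi], target_ind, other_ind)
    indi = pd.DataFrame({"PRIMARYID": ind_pid, "INDI_DRUG_SEQ": "1", "INDI_PT": ind_pt})

    # --- outcomes ----------------------------------------------------------
    n_outc = rng.choice([0, 1, 2], n, p=[0.35, 0.5, 0.15])
    outc_pid = np.repeat(primaryids, n_outc)
    outc_cod = rng.choice(_OUTC, int(n_outc.sum()), p=_OUTC_W)
    outc = pd.DataFrame({"PRIMARYID": outc_pid, "OUTC_COD": outc_cod})

    # --- demographics ------------------------------------------------------
    age_years = np.clip(rng.normal(55, 18, n), 1, 95)
    age_cod = rng.choice(["YR", "MON", "WK", "DY"], n, p=[0.92, 0.03, 0.01, 0.04])
    mult = np.select([age_cod == "MON", age_cod == "WK", age_cod == "DY"],
                     [12.0, 52.0, 365.0], 1.0)
    age_val = np.char.mod("%d", np.maximum(1, np.round(age_years * mult)).astype(int)).astype(object)
    age_val[rng.random(n) < sc.missingness.age] = ""
    age_cod = np.where(age_val == "", "", age_cod).astype(object)

    sex = rng.choice(["F", "M"], n, p=[0.52, 0.48]).astype(object)
    sex[rng.random(n) < sc.missingness.sex] = ""
    wt = np.char.mod("%.1f", np.clip(rng.normal(75, 15, n), 30, 160)).astype(object)
    wt[rng.random(n) < sc.missingness.weight] = ""
    country = rng.choice(_COUNTRIES, n, p=_COUNTRY_W).astype(object)
    country[rng.random(n) < sc.missingness.country] = ""
    occp = rng.choice(_OCCP, n, p=_OCCP_W).astype(object)
    occp[rng.random(n) < sc.missingness.occupation] = ""

    event_out = event_dt.copy().astype(object)
    miss_e = rng.random(n) < sc.missingness.event_dt
    event_out[miss_e] = ""
    part_e = (~miss_e) & (rng.random(n) < sc.partial_date_fraction)
    event_out[part_e] = np.array([s[:6] for s in event_out[part_e]], dtype=object)

    demo = pd.DataFrame({
        "PRIMARYID": primaryids, "CASEID": caseids, "FDA_DT": fda_dt,
        "EVENT_DT": event_out, "AGE": age_val, "AGE_COD": age_cod, "SEX": sex,
        "WT": wt, "REPORTER_COUNTRY": country, "OCCP_COD": occp,
    })

    # --- duplicate submissions --------------------------------------------
    n_dup = int(round(sc.duplication_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    dup_records = pd.DataFrame({
        "caseid": caseids[dup_idx],
        "original_primaryid": primaryids[dup_idx],
        "duplicate_primaryid": np.char.add(caseids[dup_idx], "2"),
    })
    if n_dup:
        tie = rng.random(n_dup) < sc.fda_dt_tie_fraction
        new_days = np.minimum(fda_days[dup_idx] + rng.integers(1, 91, n_dup), horizon)
        new_days[tie] = fda_days[dup_idx][tie]
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["PRIMARYID"] = dup_records["duplicate_primaryid"].to_numpy()
        dup_demo["FDA_DT"] = _fmt_dates(new_days, origin)
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        pid_map = dict(zip(dup_records["original_primaryid"], dup_records["duplicate_primaryid"]))
        for name, df in (("drug", drug), ("reac", reac), ("ther", ther), ("indi", indi), ("outc", outc)):
            child = df[df["PRIMARYID"].isin(pid_map)].copy()
            child["PRIMARYID"] = child["PRIMARYID"].map(pid_map)
            if name == "drug":
                drug = pd.concat([drug, child], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, child], ignore_index=True)
            elif name == "ther":
                ther = pd.concat([ther, child], ignore_index=True)
            elif name == "indi":
                indi = pd.concat([indi, child], ignore_index=True)
            else:
                outc = pd.concat([outc, child], ignore_index=True)

    # --- split into quarters by FDA_DT ------------------------------------
    full = TableBundle(demo=demo, drug=drug, reac=reac, ther=ther, indi=indi, outc=outc)
    q_of = quarter_of_date(demo["FDA_DT"])
    bundles: dict[str, TableBundle] = {}
    for quarter in quarters:
        pids = set(demo.loc[q_of == quarter, "PRIMARYID"])
        tables = {}
        for name in TABLE_NAMES:
            df = getattr(full, name)
            tables[name] = df[df["PRIMARYID"].isin(pids)].reset_index(drop=True)
        bundles[quarter] = TableBundle(**tables)

    pts = list(sc.pt_vocabulary)
    ground_truth = pd.DataFrame({
        "pt": pts,
        "soc": [sc.pt_vocabulary[p] for p in pts],
        "true_lambda": [sc.true_rate_ratio(p) for p in pts],
        "is_signal": [sc.true_rate_ratio(p) > 1 for p in pts],
    })
    return SyntheticData(scenario=sc, bundles=bundles,
                         ground_truth=ground_truth, duplicates=dup_records)


# ---------------------------------------------------------------------------
# ASCII round-trip
# ---------------------------------------------------------------------------

def write_bundle(bundle: TableBundle, directory: str | Path, quarter: str) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}{quarter}.txt"
        getattr(bundle, name).to_csv(path, sep=DELIMITER, index=False)
        paths.append(path)
    return paths


def write_quarterly_ascii(data: SyntheticData, directory: str | Path) -> list[Path]:
    """Write every quarter's tables plus the ground-truth ledger.

    Files are "$"-delimited with FAERS column headers; reading them back with
    :func:`pvsignals.io.read_quarter` reproduces the bundle exactly.
    """
    directory = Path(directory)
    paths: list[Path] = []
    for quarter, bundle in data.bundles.items():
        paths.extend(write_bundle(bundle, directory, quarter))
    gt = directory / "ground_truth.txt"
    data.ground_truth.to_csv(gt, sep="\t", index=False)
    paths.append(gt)
    dup = directory / "duplicates.txt"
    data.duplicates.to_csv(dup, sep="\t", index=False)
    paths.append(dup)
    return paths


def read_ground_truth(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "ground_truth.txt", sep="\t")
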