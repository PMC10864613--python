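"""Time-to-onset (TTO) analysis with Weibull hazard-trend classification.

TTO is the interval in days from the start of target-drug therapy
(START_DT, THER file) to the onset of the adverse event (EVENT_DT, DEMO
file), computed once per case.  Reports with missing or partial dates, or
with onset preceding the therapy start, are excluded — each exclusion reason
is counted in an audit.  A TTO of 0 days means the event occurred on the
day treatment began and is retained descriptively.

The onset distribution is summarised by median and interquartile range and
by a fixed period histogram, and modelled as Weibull(shape beta, scale
alpha): beta < 1 means a decreasing hazard over time ("early failure" —
most events shortly after initiation), beta ~ 1 a constant hazard, beta > 1
an increasing hazard ("wear-out").  The classification uses the full 95%
confidence interval of beta, not just the point estimate.  Day-0 records are
shifted to 0.5 day for fitting only, since the Weibull support is strictly
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort
from .io import parse_full_dates

__all__ = [
    "TTO_BINS",
    "WeibullFit",
    "compute_tto",
    "summarize_tto",
    "period_histogram",
    "fit_weibull",
    "classify_hazard",
]

#: histogram bin edges in days: [0-30], (30-60], (60-90], (90-180], (180-360], >360
TTO_BINS = [0, 30, 60, 90, 180, 360]
TTO_BIN_LABELS = ["0-30", "31-60", "61-90", "91-180", "181-360", ">360"]

EXCLUSION_REASONS = [
    "missing_event_dt", "partial_event_dt", "invalid_event_dt",
    "missing_start_dt", "partial_start_dt", "invalid_start_dt",
    "onset_before_start",
]


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull parameters with delta-method 95% CIs."""

    shape: float
    shape_ci: tuple[float, float]
    scale: float
    scale_ci: tuple[float, float]
    n_used: int
    log_likelihood: float
    converged: bool = True
    message: str = ""
    hazard_class: str = field(default="", init=False)

    def __post_init__(self):
        self.hazard_class = classify_hazard(self)


def compute_tto(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-case onset interval in days, with an exclusion audit.

    For each cohort case the therapy START_DT is the earliest *valid
    full-date* start among therapy rows linked (DSG_DRUG_SEQ) to the matched
    target-drug entries.  Cases whose EVENT_DT or START_DT is missing,
    partial or unparsable, or whose onset precedes the start, are excluded;
    the audit counts each reason once per case.

    Returns ``(records, audit)`` where *records* has columns ``PRIMARYID``
    and ``days`` (non-negative int).
    """
    demo = cohort.cases.demo
    audit = {r: 0 for r in EXCLUSION_REASONS}
    if demo.empty:
        return pd.DataFrame(columns=["PRIMARYID", "days"]), audit

    # therapy rows of the matched (PS, target) drug entries only
    ther = cohort.cases.ther.merge(
        cohort.matched_drug_seq,
        left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
        right_on=["PRIMARYID", "DRUG_SEQ"],
        how="inner",
    )
    start_parsed = parse_full_dates(ther["START_DT"])
    ther = ther.assign(_start=start_parsed)
    valid_start = ther.dropna(subset=["_start"]).groupby("PRIMARYID")["_start"].min()

    # classify start-date problems per case for the audit
    def _status(series: pd.Series) -> str:
        s = series.fillna("").astype(str).str.strip()
        if (s.str.fullmatch(r"\d{8}")).any():
            return "full"
        if (s.str.fullmatch(r"\d{6}|\d{4}")).any():
            return "partial"
        if (s == "").all():
            return "missing"
        return "invalid"

    start_status = (
        ther.groupby("PRIMARYID")["START_DT"].apply(_status)
        if len(ther) else pd.Series(dtype=object)
    )

    event_raw = demo.set_index("PRIMARYID")["EVENT_DT"]
    event_parsed = parse_full_dates(event_raw)

    records = []
    for pid in demo["PRIMARYID"]:
        raw_val = event_raw.loc[pid]
        ev_raw = "" if pd.isna(raw_val) else str(raw_val).strip()
        ev = event_parsed.loc[pid]
        if ev_raw == "":
            audit["missing_event_dt"] += 1
            continue
        if pd.isna(ev):
            if len(ev_raw) in (4, 6) and ev_raw.isdigit():
                audit["partial_event_dt"] += 1
            else:
                audit["invalid_event_dt"] += 1
            continue
        if pid not in valid_start.index:
            status = start_status.get(pid, "missing")
            audit[f"{status}_start_dt"] += 1
            continue
        days = (ev - valid_start.loc[pid]).days
        if days < 0:
            audit["onset_before_start"] += 1
            continue
        records.append((pid, days))

    out = pd.DataFrame(records, columns=["PRIMARYID", "days"])
    return out, audit


def summarize_tto(
    records: pd.DataFrame,
    events: pd.DataFrame | None = None,
    group_by: str = "overall",
) -> pd.DataFrame:
    """Median and IQR of onset days, overall or per SOC.

    Quantiles are linear-interpolation quantiles.  Per-SOC grouping reuses
    each case's events' SOCs (*events* must carry PRIMARYID and soc); a case
    with events in several SOCs contributes its single TTO to each.  Empty
    groups are omitted.
    """
    if group_by == "overall":
        groups = {"overall": records["days"]}
    elif group_by == "soc":
        if events is None:
            raise ValueError("per-SOC summary requires the event records")
        merged = records.merge(events[["PRIMARYID", "soc"]].drop_duplicates(),
                               on="PRIMARYID", how="inner")
        groups = {soc: g["days"] for soc, g in merged.groupby("soc")}
    else:
        raise ValueError(f"group_by must be 'overall' or 'soc', got {group_by!r}")

    rows = []
    for name, days in sorted(groups.items()):
        if len(days) == 0:
            continue
        q1, med, q3 = np.percentile(days, [25, 50, 75])
        rows.append({"group": name, "n": len(days), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])


def period_histogram(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of TTO records per fixed time period."""
    days = records["days"].to_numpy()
    edges = TTO_BINS + [np.inf]
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0:
            counts.append(int(((days >= 0) & (days <= hi)).sum()))
        else:
            counts.append(int(((days > lo) & (days <= hi)).sum()))
    total = len(days)
    return pd.DataFrame({
        "period_days": TTO_BIN_LABELS,
        "count": counts,
        "proportion": [c / total if total else np.nan for c in counts],
    })


def _weibull_nll(theta: np.ndarray, x: np.ndarray) -> float:
    log_shape, log_scale = theta
    beta, alpha = np.exp(log_shape), np.exp(log_scale)
    z = x / alpha
    return -float(np.sum(np.log(beta / alpha) + (beta - 1) * np.log(z) - z**beta))


def fit_weibull(records: pd.DataFrame | np.ndarray, min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull fit of the onset distribution.

    95% CIs come from the observed information on (log beta, log alpha)
    via the delta method, so the bounds are always positive.  Day-0 records
    are shifted to 0.5 day.  Deterministic given the records.  Fewer than
    *min_n* records is refused; degenerate samples (all values identical)
    return a non-converged fit with diagnostics instead of raising.
    """
    days = records["days"].to_numpy(dtype=float) if isinstance(records, pd.DataFrame) \
        else np.asarray(records, dtype=float)
    if len(days) < min_n:
        raise ValueError(f"need at least {min_n} records to fit, got {len(days)}")
    x = np.where(days <= 0, 0.5, days)

    if np.ptp(x) == 0:
        return WeibullFit(shape=np.nan, shape_ci=(np.nan, np.nan),
                          scale=float(x[0]), scale_ci=(np.nan, np.nan),
                          n_used=len(x), log_likelihood=np.nan, converged=False,
                          message="degenerate sample: all onset values identical")

    x0 = np.array([0.0, np.log(np.mean(x))])
    res = minimize(_weibull_nll, x0, args=(x,), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        return WeibullFit(shape=np.nan, shape_ci=(np.nan, np.nan),
                          scale=np.nan, scale_ci=(np.nan, np.nan),
                          n_used=len(x), log_likelihood=np.nan, converged=False,
                          message=f"optimizer did not converge: {res.message}")

    theta = res.x
    # observed information via central finite differences on the log scale
    h = 1e-5
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ti = np.zeros(2); ti[i] = h
            tj = np.zeros(2); tj[j] = h
            hess[i, j] = (
                _weibull_nll(theta + ti + tj, x) - _weibull_nll(theta + ti - tj, x)
                - _weibull_nll(theta - ti + tj, x) + _weibull_nll(theta - ti - tj, x)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])

    beta, alpha = np.exp(theta)
    shape_ci = (float(beta * np.exp(-1.96 * se[0])), float(beta * np.exp(1.96 * se[0])))
    scale_ci = (float(alpha * np.exp(-1.96 * se[1])), float(alpha * np.exp(1.96 * se[1])))
    return WeibullFit(shape=float(beta), shape_ci=shape_ci,
                      scale=float(alpha), scale_ci=scale_ci,
                      n_used=len(x), log_likelihood=-res.fun, converged=True)


def classify_hazard(fit: WeibullFit) -> str:
    """Hazard trend from the shape parameter's full 95% CI.

    early-failure if the CI lies entirely below 1 (decreasing hazard);
    wear-out if entirely above 1; random if the CI contains 1;
    indeterminate when the fit did not converge or the CI is undefined.
    """
    lo, hi = fit.shape_ci
    if not fit.converged or not (np.isfinite(lo) and np.isfinite(hi)):
        return "indeterminate"
    if hi < 1.0:
        return "early-failure"
    if lo > 1.0:
        return "wear-out"
    return "random"
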