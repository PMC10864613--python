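"""Disproportionality analysis: ROR, PRR + chi-square, and BCPNN IC.

Each (drug, term) pair is summarised by the 2x2 contingency table

    =============  ============  ============
                   target term   other terms
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

counted at event level (one distinct PT per case).  Three statistics are
computed per term, each with its conventional signal criterion:

* reporting odds ratio  ROR = ad/bc, Woolf 95% CI on the log scale;
  positive when the CI lower bound exceeds 1 and a >= 3;
* proportional reporting ratio  PRR = a(c+d) / c(a+b) with the plain
  Pearson chi-square (no continuity correction); positive when PRR >= 2,
  chi-square >= 4 and a >= 3;
* Bayesian confidence propagation neural network information component
  IC = log2[ a N / ((a+b)(a+c)) ]; positive when IC025, the lower bound of
  the 95% credibility interval, exceeds 0.

A term is a *consensus* signal only when all three criteria hold at once.
Consensus signals absent from the drug's label-term list are flagged as
unexpected.

The IC point estimate is reported from raw counts, exactly as the classical
formula reads.  Interval construction works on the Dirichlet(1,1,1,1)+counts
posterior of the cell probabilities: the closed form uses the exact digamma
posterior mean of IC and a trigamma variance with a delta-method covariance
correction for the overlapping margins, reported as E(IC) +/- 2*sd; the
Monte-Carlo mode samples the same posterior and takes empirical 2.5/97.5
percentiles, serving as the reference oracle for the closed form.

Zero cells make ROR/PRR undefined by default (flagged, never a crash); an
optional Haldane-Anscombe +0.5 correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "build_contingency",
    "contingency_all_terms",
    "compute_ror",
    "compute_prr",
    "compute_bcpnn",
    "evaluate_signal",
    "flag_unexpected",
    "rank_results",
    "signal_table",
    "RESULT_COLUMNS",
]

LN2 = float(np.log(2.0))

#: fixed column order of the results table, for diffability
RESULT_COLUMNS = [
    "term", "level", "a", "b", "c", "d",
    "ror", "ror_low", "ror_high", "prr", "chi2", "ic", "ic025", "ic975",
    "flag_ror", "flag_prr", "flag_bcpnn", "consensus", "expectedness",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 event counts for one (drug, term) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalStats:
    """All statistics for one term; NaN marks an undefined value."""

    ror: float = np.nan
    ror_low: float = np.nan
    ror_high: float = np.nan
    prr: float = np.nan
    chi2: float = np.nan
    ic: float = np.nan
    ic025: float = np.nan
    ic975: float = np.nan


# ---------------------------------------------------------------------------
# Contingency construction
# ---------------------------------------------------------------------------

def _term_column(level: str) -> str:
    if level == "PT":
        return "pt"
    if level == "SOC":
        return "soc"
    raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")


def build_contingency(
    target_events: pd.DataFrame,
    background_events: pd.DataFrame,
    term: str,
    level: str = "PT",
) -> ContingencyTable:
    """Count the 2x2 table for one term.

    *target_events* are the target drug's event records, *background_events*
    everyone else's; both need the column named by *level* (``pt`` or
    ``soc``).  Terms are compared case-insensitively.  A term never reported
    for the target drug yields a valid table with a = 0.
    """
    col = _term_column(level)
    t = term.strip().lower()
    a = int((target_events[col].str.lower() == t).sum())
    c = int((background_events[col].str.lower() == t).sum())
    return ContingencyTable(a=a, b=len(target_events) - a,
                            c=c, d=len(background_events) - c)


def contingency_all_terms(
    target_events: pd.DataFrame,
    background_events: pd.DataFrame,
    level: str = "PT",
) -> pd.DataFrame:
    """Vectorised tables for every term observed for the target drug.

    Returns a DataFrame with columns term, a, b, c, d; the union over rows of
    cell ``a`` equals the target drug's total event count (the terms
    partition the drug's events at either level).
    """
    col = _term_column(level)
    ta = target_events[col].value_counts()
    n_t = len(target_events)
    n_b = len(background_events)
    bg = background_events[col].value_counts()
    out = pd.DataFrame({"term": ta.index, "a": ta.to_numpy()})
    out["b"] = n_t - out["a"]
    out["c"] = out["term"].map(bg).fillna(0).astype(int)
    out["d"] = n_b - out["c"]
    return out.sort_values("term").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Statistics (vectorised over arrays of cells)
# ---------------------------------------------------------------------------

def _cells(a, b, c, d, correction: bool):
    arrs = [np.asarray(x, dtype=float) for x in (a, b, c, d)]
    if correction:
        zero = np.zeros_like(arrs[0], dtype=bool)
        for x in arrs:
            zero = zero | (x == 0)
        arrs = [np.where(zero, x + 0.5, x) for x in arrs]
    return arrs


def compute_ror(a, b, c, d, correction: bool = False):
    """ROR = ad/bc with Woolf 95% CI; NaN where a required cell is zero.

    With *correction*, tables containing a zero cell get +0.5 on all cells
    (Haldane-Anscombe) instead of being undefined.
    """
    a, b, c, d = _cells(a, b, c, d, correction)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        low = np.exp(np.log(ror) - 1.96 * se)
        high = np.exp(np.log(ror) + 1.96 * se)
    bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    ror = np.where(bad, np.nan, ror)
    return ror, np.where(bad, np.nan, low), np.where(bad, np.nan, high)


def compute_prr(a, b, c, d, correction: bool = False, yates: bool = False):
    """PRR = a(c+d)/(c(a+b)) and the Pearson chi-square on the same table.

    The chi-square is the plain (uncorrected) Pearson statistic by default;
    *yates* enables the continuity-corrected variant for sensitivity
    analysis.  PRR is NaN where its denominator vanishes; chi-square is NaN
    where a margin vanishes.
    """
    a, b, c, d = _cells(a, b, c, d, correction)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a * (c + d)) / (c * (a + b))
        diff = np.abs(a * d - b * c)
        if yates:
            diff = np.maximum(diff - n / 2, 0.0)
        chi2 = diff**2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    prr = np.where((c == 0) | (a + b == 0), np.nan, prr)
    chi2 = np.where((a + b == 0) | (c + d == 0) | (a + c == 0) | (b + d == 0), np.nan, chi2)
    return prr, chi2


def _ic_point(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(a * n / ((a + b) * (a + c)))


def compute_bcpnn(
    a, b, c, d,
    method: Literal["closed_form", "monte_carlo"] = "closed_form",
    n_draws: int = 100_000,
    seed: int = 0,
):
    """Information component with a 95% credibility interval.

    Returns ``(ic, ic025, ic975)``.  The point estimate always comes from the
    raw counts (NaN when a = 0 makes it -inf... it is reported as -inf only
    under monte_carlo; closed_form reports the prior-smoothed posterior mean
    there so the value stays finite).  Interval bounds come from the
    Dirichlet(1,1,1,1)+counts posterior: moment-based normal approximation
    (closed_form, reported as E +/- 2 sd) or empirical posterior percentiles
    (monte_carlo).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ic_raw = _ic_point(a, b, c, d)

    a1, b1, c1, d1 = a + 1, b + 1, c + 1, d + 1
    total = a1 + b1 + c1 + d1
    m12 = a1 + b1   # posterior Dirichlet mass of the drug margin
    m13 = a1 + c1   # ... of the term margin
    e_ic = (psi(a1) - psi(m12) - psi(m13) + psi(total)) / LN2
    if method == "closed_form":
        # Var(ln p11 - ln p1. - ln p.1) with exact trigamma variances and a
        # delta-method covariance for the two overlapping margins.
        cov_margins = (a1 * total - m12 * m13) / (m12 * m13 * (total + 1))
        var = (polygamma(1, a1) - polygamma(1, m12) - polygamma(1, m13)
               + polygamma(1, total) + 2 * cov_margins) / LN2**2
        sd = np.sqrt(np.maximum(var, 0.0))
        ic025, ic975 = e_ic - 2 * sd, e_ic + 2 * sd
        ic = np.where(np.isfinite(ic_raw), ic_raw, e_ic)
        return ic, ic025, ic975
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        alphas = np.stack(np.broadcast_arrays(a1, b1, c1, d1), axis=-1).reshape(-1, 4)
        lows = np.empty(len(alphas))
        highs = np.empty(len(alphas))
        for i, al in enumerate(alphas):
            p = rng.dirichlet(al, n_draws)
            ic_draws = np.log2(p[:, 0] / ((p[:, 0] + p[:, 1]) * (p[:, 0] + p[:, 2])))
            lows[i], highs[i] = np.percentile(ic_draws, [2.5, 97.5])
        shape = np.broadcast(a, b, c, d).shape
        return (ic_raw.reshape(shape),
                lows.reshape(shape) if shape else float(lows[0]),
                highs.reshape(shape) if shape else float(highs[0]))
    raise ValueError(f"unknown BCPNN method {method!r}")


def compute_stats(
    table: ContingencyTable,
    correction: bool = False,
    yates: bool = False,
    bcpnn_method: Literal["closed_form", "monte_carlo"] = "closed_form",
    seed: int = 0,
) -> SignalStats:
    """All three algorithms on one table."""
    ror, low, high = compute_ror(table.a, table.b, table.c, table.d, correction)
    prr, chi2 = compute_prr(table.a, table.b, table.c, table.d, correction, yates)
    ic, ic025, ic975 = compute_bcpnn(table.a, table.b, table.c, table.d,
                                     method=bcpnn_method, seed=seed)
    return SignalStats(ror=float(ror), ror_low=float(low), ror_high=float(high),
                       prr=float(prr), chi2=float(chi2),
                       ic=float(ic), ic025=float(ic025), ic975=float(ic975))


# ---------------------------------------------------------------------------
# Criteria, consensus, expectedness, ranking
# ---------------------------------------------------------------------------

def evaluate_signal(a, ror_low, prr, chi2, ic025):
    """Per-algorithm positivity flags and their conjunction.

    The report-count criterion ("N >= 3") is evaluated on cell a, the number
    of target-drug reports of the term.  Undefined statistics (NaN) never
    flag positive.
    """
    a = np.asarray(a, dtype=float)
    ror_low = np.asarray(ror_low, dtype=float)
    prr = np.asarray(prr, dtype=float)
    chi2 = np.asarray(chi2, dtype=float)
    ic025 = np.asarray(ic025, dtype=float)
    with np.errstate(invalid="ignore"):
        flag_ror = np.nan_to_num(ror_low, nan=-np.inf) > 1.0
        flag_ror &= a >= 3
        flag_prr = (np.nan_to_num(prr, nan=-np.inf) >= 2.0) \
            & (np.nan_to_num(chi2, nan=-np.inf) >= 4.0) & (a >= 3)
        flag_bcpnn = np.nan_to_num(ic025, nan=-np.inf) > 0.0
    return flag_ror, flag_prr, flag_bcpnn, flag_ror & flag_prr & flag_bcpnn


def flag_unexpected(results: pd.DataFrame, label_terms: Iterable[str] | None) -> pd.DataFrame:
    """Annotate consensus signals as expected/unexpected against label terms.

    Terms in the drug's product label are *expected*; consensus signals
    absent from it are *unexpected*.  Non-consensus terms get ``"n/a"``.
    With no label list every term is ``"unknown"``.
    """
    out = results.copy()
    if label_terms is None:
        out["expectedness"] = "unknown"
        return out
    labels = {str(t).strip().lower() for t in label_terms}
    is_expected = out["term"].str.strip().str.lower().isin(labels)
    out["expectedness"] = np.where(
        ~out["consensus"], "n/a", np.where(is_expected, "expected", "unexpected"))
    return out


def rank_results(results: pd.DataFrame, key: Literal["case_number", "ic025"] = "case_number") -> pd.DataFrame:
    """Stable descending sort by case count a or IC025; ties alphabetical."""
    col = {"case_number": "a", "ic025": "ic025"}[key]
    return results.sort_values([col, "term"], ascending=[False, True],
                               kind="mergesort").reset_index(drop=True)


def signal_table(
    target_events: pd.DataFrame,
    background_events: pd.DataFrame,
    level: str = "PT",
    label_terms: Iterable[str] | None = None,
    correction: bool = False,
    yates: bool = False,
    bcpnn_method: Literal["closed_form", "monte_carlo"] = "closed_form",
    seed: int = 0,
) -> pd.DataFrame:
    """Full disproportionality screen at one MedDRA level.

    Builds every term's 2x2 table, computes the three algorithms, evaluates
    the per-algorithm criteria and the consensus rule, and annotates
    expectedness.  Column order is fixed (:data:`RESULT_COLUMNS`).
    """
    tables = contingency_all_terms(target_events, background_events, level)
    if tables.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    a, b, c, d = (tables[x].to_numpy() for x in "abcd")
    ror, ror_low, ror_high = compute_ror(a, b, c, d, correction)
    prr, chi2 = compute_prr(a, b, c, d, correction, yates)
    ic, ic025, ic975 = compute_bcpnn(a, b, c, d, method=bcpnn_method, seed=seed)
    flag_ror, flag_prr, flag_bcpnn, consensus = evaluate_signal(a, ror_low, prr, chi2, ic025)
    out = tables.assign(
        level=level, ror=ror, ror_low=ror_low, ror_high=ror_high, prr=prr,
        chi2=chi2, ic=ic, ic025=ic025, ic975=ic975, flag_ror=flag_ror,
        flag_prr=flag_prr, flag_bcpnn=flag_bcpnn, consensus=consensus,
    )
    out = flag_unexpected(out, label_terms)
    return out[RESULT_COLUMNS]
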