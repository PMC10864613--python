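# Methods

## The analysis model

Spontaneous-report disproportionality compares how often a (drug, event)
pair is reported against the background of all other drugs and events in
the same database window. For each term *t* (a MedDRA preferred term, PT,
or its System Organ Class, SOC) and target drug, events are cross-tabulated
as a 2×2 table: a = target drug with *t*, b = target drug with other terms,
c = other drugs with *t*, d = other drugs with other terms. The counting
unit is the *event*: one record per distinct PT per case. Repeated
identical PTs inside one report count once — this is the convention under
which published per-SOC counts for the NTRK-inhibitor cohorts sum exactly
to the drug-level PT totals (1,605 and 1,343), which is why it is the
default and the only supported convention.

Three statistics are computed per term, with their conventional signal
thresholds (reporting odds ratio with Woolf CI; proportional reporting
ratio with plain Pearson χ²; BCPNN information component with IC025 > 0),
and a term is called a signal only on the conjunction of all three. The
"N ≥ 3" report-count condition in the ROR/PRR criteria is read as a ≥ 3,
the target-drug report count of the term, the usual convention in
disproportionality reporting.

Assumptions worth keeping in mind: reports are treated as independent;
the background ("all other drugs") is every event in the window whose case
is not in the target cohort, regardless of the role code the other drugs
carry; and no shrinkage or multiplicity adjustment is applied beyond the
consensus rule itself — the three-way conjunction is the paper-trail
convention in this literature, not a calibrated error-rate control.

## BCPNN interval construction

The classical IC point estimate log₂(a·N/((a+b)(a+c))) is reported from the
raw counts. For the credibility interval the four cell probabilities are
given a Dirichlet(1,1,1,1) prior, so the posterior is
Dirichlet(a+1, b+1, c+1, d+1). Two interval modes are provided:

* **closed_form** (default): E(IC) is the exact posterior mean, computed
  with digamma functions, E(IC)·ln2 = ψ(a+1) − ψ(a+b+2) − ψ(a+c+2) +
  ψ(N+4). V(IC) combines the exact trigamma variances of the three log
  terms with a delta-method covariance for the two overlapping margins
  (they share cell a). The reported bounds are E(IC) ± 2·√V(IC), the
  two-sided convention this literature prints.
* **monte_carlo**: direct posterior sampling, bounds as empirical 2.5/97.5
  percentiles. This mode is the reference oracle: for tables with all
  cells ≥ 5 the closed form agrees with a 100,000-draw Monte-Carlo
  quantile within 0.1 on IC025 (typically within 0.02; the worst case is
  the smallest admissible all-cells-5 table, where posterior skewness
  costs ≈0.09).

With a = 0 the raw IC is −∞; the closed form then reports the
prior-smoothed posterior mean so that the value stays finite, and the term
cannot flag (IC025 < 0 there by construction).

Zero cells leave ROR and PRR undefined (flagged, never raised); the
optional Haldane–Anscombe correction adds 0.5 to every cell of affected
tables. χ² is the uncorrected Pearson statistic, identical to the
expected-count formulation to 1e-9; a Yates-corrected variant exists as a
sensitivity switch only.

A caveat on monotonicity: ROR and PRR increase strictly with a (holding
b, c, d fixed) everywhere, but the raw IC does not — for a large relative
to its margins, adding a joint event inflates N and both margins enough to
*lower* IC (e.g. (100,1,1,1000) → (101,1,1,1000)). In the sparse-signal
regime a < min(b, c), where signal detection actually operates, IC is
strictly increasing; the property tests assert exactly that.

## Deduplication

Quarterly re-submissions are collapsed to one version per CASEID: keep the
maximal (FDA_DT, PRIMARYID) lexicographically, with a missing FDA_DT
ordering before any real date (an unknown date cannot be "most recent"),
and PRIMARYIDs compared numerically when both parse as integers. The
operation is idempotent and order-invariant; an audit table records every
removed version with its winner. The per-drug quarter window is applied
*after* deduplication, so a case re-submitted across a window boundary is
first reduced to its latest version and only then window-tested.

## Time to onset

TTO is computed once per case: EVENT_DT minus the earliest *valid
full-date* therapy start among THER rows linked to the matched
primary-suspect drug entries. Cases with missing, partial (YYYYMM or
YYYY), or unparsable dates, or onset before start, are excluded with
per-reason audit counts; day-0 onsets are kept (event on the first day of
therapy). The Weibull fit maximises the likelihood in (log β, log α) by
Nelder-Mead; 95% CIs come from the observed information (central finite
differences) on the log scale via the delta method, which keeps the bounds
positive and the fit deterministic. Day-0 records are shifted to 0.5 day
for fitting only, since the Weibull support is strictly positive. Hazard
classification uses the whole CI of β: early-failure only when the CI lies
entirely below 1, wear-out only when entirely above, random when it
straddles 1. Intervals are whole days, which biases β̂ slightly upward for
heavily left-concentrated data (≈5–9% at shape 0.56, scale 30 d); the fit
is of the same day-resolution data the descriptive statistics use.

## The synthetic generator

`SyntheticScenario` defines one simulated reporting stream. Cases draw a
primary-suspect drug (target with probability `target_share`), a
truncated-geometric number of reaction slots (support 1–10), and each slot
draws a PT from a Zipf-like background categorical; for target cases the
planted terms' weights are multiplied by their rate ratio λ and the
distribution renormalised. Duplicate submissions clone a case under a
higher PRIMARYID with a later (or, for a configurable tie fraction, equal)
FDA_DT. Onsets are Weibull; EVENT_DT = START_DT + onset; FDA_DT follows
after a short reporting delay and drives the quarterly split. Dates are
blanked or truncated to YYYYMM at configurable rates; demographics are
blanked at baseline-table-like rates. Output is byte-identical for a fixed
seed, and a ground-truth ledger (true λ per PT, duplicate pairs) is
emitted alongside.

Defaults are set once to study-like conditions: 50,000 reports over
2019Q3–2023Q1; target share 0.011 (≈550 PS cases, the scale of the
published NTRK-inhibitor cohorts); mean ≈2.6 PTs per case (matching
1,343/524 ≈ 2.56 events per report); onset Weibull(0.56, 30 d), whose
median ≈15.6 d matches the published 16-day median; age unknown 90%,
weight unknown 80%, sex unknown 10%, event/start dates missing 35% each
with 5% partial; duplication rate 8% with 15% FDA_DT ties. Planted
signals: λ = 8, 6, 4, 4 on four terms plus one weak λ = 2 term that is
*not* expected to reach consensus reliably.

Because planting multiplies weights and renormalises, the realised
event-level rate ratio is λ/Z with Z = 1 + Σᵢ rᵢ(λᵢ−1) ≈ 1.12 under the
defaults: the λ = 8 term realises ≈7, and null terms realise ≈0.9 rather
than exactly 1. The planted terms are pinned to mid-tail background ranks
precisely to keep Z small. Tests that score the generator against its own
parameters use these renormalised targets' stated tolerance bands (±20%
planted, ±15% null).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: reporting-rate drift over calendar time, drug-
and country-specific reporting cultures, correlated PT co-reporting
(syndromes), duplicate reports under *different* CASEIDs, narrative
fields, and confounding by indication beyond the simple indication-term
mechanism. Recovery results on synthetic data bound what the code can do,
not what FAERS data will yield.

## Numerical and design choices

* Percentages are rounded half-up to one decimal (`Decimal`, not banker's
  rounding): this is the convention under which the published baseline
  tables recompute from their printed counts. Serious-outcome percentages
  use the total of outcome *entries* as denominator, since a case can
  carry several outcome codes.
* Age is normalised to years from AGE/AGE_COD (YR×1, DEC×10, MON÷12,
  WK÷52, DY÷365; unknown codes → missing); weights are assumed kilograms.
  Bands: age <18 / 18–64 / >64; weight <80 / 80–100 / >100 kg.
* Drug matching trims and case-folds, then matches the whole string by
  default; a word-boundary substring mode catches salt forms
  ("LAROTRECTINIB MESYLATE") at the cost of occasional over-matching.
* Indication exclusion is exact PT equality after case-folding; the
  default exclusion list is data-driven (the INDI_PT values observed for
  the target drug) and can be overridden in config.
* PT→SOC mapping is a user-supplied two-column file (MedDRA itself is
  licensed); unmapped PTs fall into an "UNMAPPED" bucket and are counted,
  so event totals are conserved.
* Ranking of signal tables is a stable descending sort by case count or
  IC025 with alphabetical tie-break, making outputs diffable; the results
  table has a fixed column order for the same reason.
* Problem sizes in the test and acceptance suites: recovery uses twenty
  50,000-report scenarios; the BCPNN oracle uses 100,000 posterior draws;
  Weibull coverage uses 200 replicates at n = 1,000. These sizes give
  comfortable Monte-Carlo margins for the tolerances asserted while
  keeping a full run around a minute.

## Known limitations

* Only exact-key deduplication is implemented; probabilistic record
  linkage across CASEIDs is out of scope.
* The multi-axial MedDRA hierarchy is reduced to a primary-SOC map;
  secondary SOC links are not modelled.
* No EBGM/MGPS gamma-Poisson shrinkage, sequence-symmetry analysis, or
  regression-based confounding adjustment.
* TTO modelling ignores censoring and competing risks; reports without a
  valid therapy start simply leave the analysis, which can bias onset
  summaries if missingness correlates with onset time.
* Expectedness flags are only as good as the supplied label-term list;
  with none supplied the pipeline reports "unknown" rather than guessing.
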