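# Methods

## Design

The pipeline implements a nested case–control design on longitudinal
prescription-claims records. The unit of analysis is the participant: one
index episode per participant, anchored at the first index-drug
prescription. Because claims data record prescriptions rather than clinical
events, the outcome is a *surrogate*: a prescription of one of four
anti-allergic marker drugs (promethazine, dexamethasone, calcium gluconate,
adrenaline) is read as a suspected allergic reaction. All temporal logic is
day-granular — dates are integer day indices (days since 1970-01-01) and
every window is integer arithmetic — because claims carry no time-of-day.

## Case ascertainment

A marker prescription on day *m* is **incident** when (a) at least
`washout_days` (default 30, the day-granular reading of a one-month
waiting time) of observation precede it, and (b) no marker prescription
falls in `[m − washout_days, m − 1]`. The earliest incident marker is
classified by its offset *d* from the index date:

| outcome | rule |
|---|---|
| primary case | 1 ≤ d ≤ 3 |
| expanded (same-day) case | d = 0 and no index-drug prescription on day +1 |
| excluded | d = 0 with the index drug continued on day +1; d < 0; d > 3 |
| control-eligible | no incident marker |

The 0–3-day window reflects the clinical observation that allergic
reactions to the index drug occur mostly within 24 h of administration.
The same-day exclusions exist because prescription order within a day is
unobservable; the expanded definition re-admits same-day patients whose
index drug was stopped the next day (read as the prescriber reacting to an
allergy) and is used for sensitivity analyses. Classification is total:
every cohort member lands in exactly one of six buckets, and the run
manifest asserts that the buckets partition the cohort.

Two points are deliberate operational choices. The washout is anchored to
the participant's observation start (conditions a + b above); anchoring to
prior marker-free time only is available via the `washout_days` parameter
semantics and the conditions are documented in
`find_incident_marker`. Controls are cohort members with *no qualifying
incident marker at all* — including participants whose only markers fall
inside the washout runway; participants excluded for marker timing appear
on neither side. The claims CSV carries no enrollment dates, so the
observation window defaults to the file-wide date range (a calendar-window
reading appropriate for single-year claims extracts) and can be overridden
per call.

## Propensity model and matching

Case status is modelled by logistic regression on age (continuous), gender,
visit setting, and hospital level (tertiary reference — the choice of
reference does not affect the outcome model). The fit is plain IRLS with
convergence at max-score < 1e-8 within 100 iterations; perfect separation
raises an error naming the separating covariate rather than returning
divergent coefficients. Constant covariate columns are dropped from the fit
and their coefficients pinned at zero (intercept-only degenerate inputs are
then exact: every score equals the case fraction).

Matching is greedy 1:1 without replacement on the probability scale, cases
in descending propensity score, ties broken by ascending participant id on
both sides, so results are invariant to input row order. No caliper is
applied by default; an optional probability-scale caliper leaves
out-of-range cases unmatched and reported. Greedy matching is not globally
optimal — a test documents that its total distance can exceed the optimal
assignment's — but it is the convention this design follows. Covariate
balance is reported as standardized mean differences (pooled-SD
denominator), with age rendered `mean ± SD` and categorical levels as
`n (%)`.

## Estimators

*Exposure* is a same-date co-prescription of a target drug with the index
prescription; marker drugs are never exposures. For cases, same-date coding
automatically satisfies "no later than the marker prescription" (asserted
at coding time).

- **Crude OR**: cross-product `(a·d)/(b·c)` with Woolf CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` and Wald p. Any zero cell makes
  the estimate undefined and reports render an em dash; the
  Haldane–Anscombe +0.5 correction is opt-in (`zero_cell="haldane"`).
- **Discordant-pair OR**: `n10/n01` with the analogous log-scale CI and an
  exact McNemar p (doubled binomial tail at ½, capped at 1).
- **Conditional logistic regression**: the 1:1 matched-pair conditional
  likelihood in pair-difference form, maximised by Newton–Raphson
  (gradient tolerance 1e-8, 200-iteration cap, steps damped to max-norm 5
  far from the optimum), covariance from the inverse observed information.
  Drugs with zero discordance, monotone discordance (infinite MLE), or
  exactly collinear difference columns are rejected with the offending
  drugs named — unconverged estimates are never returned. For a single
  binary exposure the estimate equals `ln(n10/n01)`; the test-suite checks
  this identity to 1e-8 and checks the maximiser against an independent
  BFGS oracle and a likelihood grid.
- **Backward selection**: iterative single-removal of the largest Wald
  p > α (default 0.05), refitting after each removal; drugs that cannot
  enter the model are pre-dropped and logged, and drugs whose coefficients
  diverge under joint quasi-separation mid-selection are dropped with a
  logged attribution. The final model is reported sorted by descending OR.
  Wald-based elimination is the common default; no multiple-testing
  correction is applied (a note to this effect accompanies the CLI report).
- **Concomitant-count contrast**: the per-arm distribution of the number of
  target drugs used, plus the crude OR for ≥1 vs 0.
- **Subgroups**: pairs are stratified by the case member's age band
  (<18, 18–64, ≥65) or gender and re-analysed with the same machinery;
  strata with fewer than `min_discordant_pairs` (default 10) discordant
  pairs report "insufficient data" instead of estimates.

Univariate reports include both the crude and the discordant-pair
estimator. The two do not coincide in general, and published univariate
tables in this design are not always internally consistent with a single
choice; reporting both makes the discrepancy visible instead of resolving
it silently.

## Synthetic data generator

The generator produces one index episode per participant: demographics
(three-component age mixture with child/adult/elderly modes weighted
0.43/0.37/0.20; 47% female; 76% inpatient; hospital levels 26/52/22%),
an index date uniform in the observation year, per-drug same-day
co-prescription from a logistic model (default prevalences mirror the
frequency ordering of the motivating study's univariate table, from ~25%
for ambroxol down to ~0.2% for meropenem), and a per-participant allergy
indicator with
`logit p = baseline + Σ_drug β_drug·exposed_drug + Σ_cov γ_cov·cov`.
Allergic participants receive one marker prescription at an offset drawn
from `{0: .40, 1: .40, 2: .15, 3: .05}` (most reactions within a day);
same-day markers re-prescribe the index drug next day with probability 0.5,
exercising the same-day exclusion and the expanded definition. Background
marker prescriptions arrive at 6×10⁻⁴ per participant-day, scattered over
the whole window, so washout and timing exclusions fire on realistic noise.
The defaults (`baseline_allergy_logodds = logit(0.02)`, the planted effect
profile of the motivating study) put the generated flowchart close to the
published one: ~77% of the cohort marker-free, ~21% incident markers, and
final primary cases a few percent of the cohort.

Covariate effects enter both co-prescription *and* allergy risk (defaults
`age_z: 0.3/0.2`, `inpatient: 0.5/0.3`). Both paths are needed for the
covariates to be genuine confounders — with an exposure-only path the
matching step would have nothing to correct — and the balance tests verify
empirically that matching shrinks covariate SMDs under strong confounding.
The config field `same_day_marker_fraction` is derived from the delay
distribution's mass at zero rather than stored separately, so the two
cannot disagree.

A separate pair-level simulator (`simulate_matched_pairs`) draws both
members' exposures independently and assigns case status from the
conditional pair-level model, making the planted conditional OR exact by
construction; it is the workhorse for parameter-recovery and oracle tests
where cohort-level machinery would only add noise.

What the generator does **not** emulate: repeat index episodes, dose /
route / duration, drug-drug correlation structure beyond shared covariate
effects, time-varying prescribing, informative censoring, or marker
prescriptions written for non-allergy indications of the same drugs (e.g.
dexamethasone as co-therapy). Passing tests therefore show the pipeline's
logic and estimators are correct under the stated assumptions — not that
the surrogate definition is clinically valid on real data.

## Problem sizes used in validation

Parameter recovery uses 100 replicates of 2,000 pairs with planted ORs
4.0 / 2.8 / 1.5 (medians required within ±20% of truth). Null calibration
uses 500 pipeline replicates of a 4,000-participant no-effect scenario with
uniform 20% co-prescription prevalence — sized so per-cell counts are large
enough for the Wald 2×2 test to be near-nominal, which is what makes the
false-positive rate a check of the pipeline rather than of small-sample
Wald behaviour — and requires the per-drug false-positive fraction to lie
in the 95% binomial band around 5%. Worked-example quantities from the
motivating study's printed tables (crude ORs, the ≥1-vs-0 contrast of
1.92, the 7.7% flowchart ratio) are recomputed exactly from the printed
counts.

## Known limitations

- The surrogate outcome misclassifies allergies treated without the four
  markers, and background marker prescriptions can create false cases;
  the washout and timing rules reduce but do not eliminate this.
- Greedy matching can be suboptimal and, with a caliper, can leave cases
  unmatched; no optimal-assignment matcher is provided.
- Backward selection inherits the usual instability of stepwise methods;
  retained null drugs at roughly the α rate are expected.
- The conditional model adjusts only for the 25 exposure indicators;
  residual confounding by unmeasured covariates is out of scope, as is any
  mechanistic interpretation of the estimated associations.
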