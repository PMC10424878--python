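# Methods

## The prospective SIRS rule engine

The engine turns an irregularly sampled chart-event stream into per-minute
validity of the four SIRS criteria — tachycardia (TC), tachypnea (TP),
abnormal temperature (Tem), abnormal leukocyte count (Leu) — under one
overarching frame: a measurement outside its normal range opens criterion
validity at its chart minute, a subsequent measurement re-evaluates it
(in-range, zero dose, or zero expired minute volume terminates validity),
and validity never outlasts a criterion-specific maximum length.  All times
are floored to an integer minute grid; intervals are half-open `[a, b)`,
so a record at minute t affects minute t and a terminating record at minute
u makes the criterion false from u on.  Because records only ever act
forward in time, the algorithm is strictly prospective: truncating the
stream at minute t never changes any level at or before t.  This property is
asserted by a dedicated test and is what makes the engine usable on live
data streams.

Assumptions worth stating explicitly:

* Records are taken at face value; no smoothing, imputation or plausibility
  modelling beyond the temperature artifact filter (records ≤ 29 °C or
  ≥ 42.5 °C are discarded as sensor artifacts).
* The three catecholamines are tracked as independent streams: a positive
  dose of any drug fulfils the sub-criterion, and only a zero record of the
  *same* drug terminates it.  Rationale: the criterion reads on the total
  dose, but the drugs are charted asynchronously, and any positive component
  keeps the total positive.
* "Within the preceding hour" for the ventilation suppression of the
  respiratory-rate and PaCO2 sub-criteria is the closed lookback `[t-60, t]`
  in minutes, irrespective of same-minute charting order.
* Same-minute records of one parameter are resolved by charting order: the
  later record is the current one.  Whether an abnormal record charted in
  the same minute as a terminating record re-opens validity is therefore an
  input-order question; both orders behave consistently and are tested.
* The catecholamine maximum validity defaults to 60 min; a 30-min reading
  of the same rule circulates, so the length is configurable
  (`RuleConfig.catecholamine_validity`) and both values are covered by tests.
* The `non_icu` variant removes the ICU-specific machinery (catecholamine
  and EMV sub-criteria, EMV suppression/termination); temperature and
  leukocyte rules are untouched, which is why prospective and non-ICU runs
  coincide exactly for weighting schemes with zero TC and TP weight.

## Levels, weights and descriptors

The per-minute level is λ = Σ_c w_c 𝟙_c with non-negative weights summing
to 1.  Weights are exact `Fraction`s; a level series is stored as integer
numerators over the scheme's least common denominator.  This makes the
change count C exact (it counts rule-state changes, never floating-point
noise) and makes level quantization assertable: attained levels are subset
sums of the scheme's weights, and under equal weighting λ ∈
{0, ¼, ½, ¾, 1} maps one-to-one to the number of concurrently fulfilled
criteria.  The 43 schemes are enumerated in six composition types
(1 + 4 + 6 + 4 + 4 + 24); within each type they are ordered
lexicographically by descending weight tuple, which reproduces every id
anchor fixed by usage (ws1 equal; ws2/ws3/ws4/ws5 one-hot TC/TP/Tem/Leu;
ws11 the Tem+Leu pair; ws18 temperature-dominant ½ with ⅙ elsewhere).  Ids
beyond those anchors are a convention of this package; every API accepts an
explicit weight tuple so no analysis needs to rely on the id mapping.

A window of L consecutive minutes (default 1440 = 24 h) is summarised by
Λ (mean level), Δ = λ_L − λ_1 and C = #{ℓ : λ_ℓ ≠ λ_{ℓ+1}}.  λ_1 is the
first minute of the window even if little data precede it; the resulting
admission-edge inflation of C (parameters are first charted at slightly
different minutes) is a property of real charting too and is deliberately
not corrected.  Criterion validity that started before the window persists
into it (the engine keeps a lookback of each criterion's maximum validity
length).

## Task construction

*Prediction*: one row per encounter over `[admission, admission+1440)`;
outcome is the sepsis-ever flag regardless of follow-up time; the
time-to-event T (onset − admission for cases, end − admission otherwise)
supports the Cox model.

*Diagnosis*: nested case-control.  For each septic case with treatment
duration τ = onset − admission, the risk set contains all other admissions
with stay ≥ τ; each control's index time is its own admission + τ, and its
window is the last 24 h before that index.  A control can appear in many
risk sets at different index times.  Cases with identical τ have identical
risk sets and share one stratum; their control rows are emitted once per
stratum so no (encounter, index) pair repeats.  By default an encounter
already septic by τ after its own admission is not an eligible control (the
at-risk convention); `strict_at_risk=False` selects the permissive
stay-only reading.  Logistic fits on the diagnosis rows ignore strata and
control multiplicity (plain logistic regression, no imbalance correction);
a conditional-logistic treatment is out of scope.

## Evaluation

Seven logistic models (all non-empty subsets of {Λ, Δ, C}, intercept always
included) are fitted by unpenalized maximum likelihood (statsmodels); folds
are stratified 10-fold with a recorded seed, and the pooled out-of-fold
probabilities give one AUROC per cell.  Sensitivity and specificity are
reported at the probability cutoff maximising their sum, taking the lowest
such cutoff on ties.  Calibration is a logistic recalibration of the
outcome on the predicted log-odds; slope and intercept have ideal values 1
and 0, and DistSlope/DistIntercept are the absolute deviations.
Probabilities at {0, 1} are clipped at 1e−12 with a warning.  Under perfect
separation the fit falls back to a mildly ridge-stabilised logistic
regression (flagged in the result; Wald intervals are then not reported).

Ranking scores: within each contributing model, schemes are ranked by AUROC
with mid-ranks for ties and the rank is normalized to [0, 1] (best = 1);
s_w is the mean over the contributing models, s_m the analogous mean of
within-scheme model ranks over all schemes.  The score is invariant under
strictly monotone transforms of the AUROCs and satisfies the anchor
properties (best-everywhere → 1, worst-everywhere → 0).

The Cox proportional-hazards model (T, S) ~ Λ + Δ + C uses the lifelines
partial-likelihood fit; constant predictors are dropped with a flag, and
the omnibus test is the likelihood-ratio test of all descriptor
coefficients being zero.  Group comparisons use the two-sided Wilcoxon
rank-sum test per descriptor (mean ± sd layout) and per-combination χ²
tests on person-minute counts.

## Synthetic cohort generator

The generator emulates a post-surgical polytrauma ICU cohort at the level
the rule engine reads — no waveform or organ-system modelling.  Defaults:
415 encounters, 34% septic; length-of-stay log-normal with moments matched
to 25.4 ± 17.8 days (septic) and 8.5 ± 6.8 days (non-septic), floored at
24 h + 1 min; sepsis onset uniform between 24 h after admission and
discharge.  Charting cadences (mean inter-record gaps, exponential):
heart rate and SpO2 5 min, EMV 5 min during ventilation episodes,
respiratory rate 15 min off ventilation, temperature 2 h, PaCO2 6 h,
leukocytes 24 h; catecholamine doses at therapy start, hourly during
therapy, and a zero record at stop.  Baseline values are normal
distributions with a per-patient offset and AR(1) noise (φ = 0.85 between
consecutive records), chosen so vitals persist near or across thresholds
the way autocorrelated physiology does rather than flapping independently
every few minutes.  Ventilation (60% of encounters) starts within 12 h of
admission, catecholamine therapy (30%) within 2 days; the offsets are
absolute rather than stay-proportional so that the law of the first-day
event stream is identical across outcome groups — this is what makes the
null mode exactly exchangeable, a property the calibration tests rely on.

The sepsis effect has two parts, both acting through *values* (never by
toggling criterion states), so the rule engine is exercised end to end:
an acute uplift inside `[onset − 1440, onset)` replaces charted values by
out-of-range draws with per-criterion probabilities (defaults 0.3–0.4, plus
a 0.3 chance of pre-onset ventilation), and a mild chronic uplift (0.12)
elevates abnormality throughout a septic encounter's stay, reflecting the
stronger post-trauma inflammatory response of patients who go on to develop
sepsis.  Null mode sets every uplift to zero.  `chart_horizon` optionally
caps event generation at admission + H minutes purely for speed in analyses
that only read an early window; manifest times are unaffected.

What passing tests on this generator do **not** show: real chart data have
missingness patterns, device artifacts, treatment feedback loops and
nonstationary baselines that the generator does not model, so absolute
performance numbers on synthetic cohorts say nothing about clinical
performance — only the relative, structural properties (prospectivity,
variant coincidence, calibration of the machinery, sign recovery under a
known effect) transfer.

## Problem sizes and numerical conventions

Statistical tests run at reduced, stated sizes chosen by this package: the
rule-engine/oracle equivalence uses 100 random encounters × 4 criteria on a
6-h horizon; null calibration uses 50 seeds × 400 encounters (the pooled
out-of-fold AUROC carries a small inherent pessimistic bias under the null,
about 0.49 independent of n, which the stated ±0.02 band accommodates);
parameter recovery uses 20 seeds × 300 encounters with a stated strong
uplift (acute 0.6–0.8, chronic 0.25) because the multivariable Cox fit
adjusts for the correlated descriptors Δ and C and needs a clear signal for
per-seed sign recovery.  Weighted levels are computed in integer arithmetic
and emitted as floats; equality tests for C always use the integer
numerators.  Degenerate inputs: windows shorter than 2 minutes have no
Δ/C; single-class outcomes, all-censored survival data and constant
predictors raise or are flagged rather than silently fitted.

## Known limitations

* The retrospective reference variant of the algorithm (which may consult
  future records) is not implemented; its rules are not specified in a
  reproducible way.
* The leukocyte immature-band-forms sub-criterion is deliberately omitted.
* Risk-set eligibility measures "treated at least as long" on total stay
  for septic candidate controls (literal reading); time-to-own-onset
  matching is available only through the strict at-risk clause.
* The ranking score is this package's normalized-rank construction; it
  satisfies the published anchor values but other constructions satisfying
  the same anchors exist.
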