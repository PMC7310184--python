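# Methods

## Data model and cohort reconstruction

The unit of analysis is one patient at bedside evaluation for unplanned
surgical ICU admission, carrying a single integer MEWS `s ≥ 0` and a
binary vital status (deceased = 1, the modelled event). The packaged
reference dataset is not patient-level: it is the cumulative
cross-classification of the rule "predict death iff `s ≥ T`" at every
threshold `T = 8 … 0` for a 263-patient series. Because
`TP[T] = Σ_{s≥T} deaths[s]` and `FP[T] = Σ_{s≥T} survivors[s]`, first
differencing (`deaths[s] = TP[s] − TP[s+1]`, likewise survivors from FP)
recovers the per-score outcome counts exactly, and expanding those counts
gives a cohort that is unique up to record identity. The expansion is
canonical — ascending score, deceased before alive, sequential synthetic
identifiers — so reconstruction is byte-reproducible. Tables are
validated on construction (constant class margins, cumulative columns
non-increasing in T, and `TP = total deceased`, `TN = 0` at threshold 0);
when a table's minimum threshold exceeds 0 the outcome mass below it is
not identifiable score-by-score and is placed at one score below that
threshold, which preserves exact forward re-cumulation over the table's
own rows.

Score range is never hard-coded: `S_max` is inferred from the data
(observed range 0–8 in the reference series, but MEWS can exceed 8 under
other bandings).

## Scoring (optional stage)

MEWS banding differs between institutions, so the scoring table is
configuration: per-component half-open `[lo, hi)` bands worth 0–3 points
plus an explicit AVPU map, validated to tile a plausible physiological
range (HR 10–300 /min, RR 0–80 /min, SBP 20–300 mmHg, temperature
25–45 °C). A widely used default banding ships as
`data/mews_bands.json` (maximum total 14). Temperature is Celsius only;
Fahrenheit-scale values fall outside the plausibility bounds and are
rejected rather than converted. The prognostic analysis consumes
already-computed scores, so nothing downstream depends on the banding
choice.

## Prognostic model

`logit Pr(death | s) = β₀ + β₁ s`, fitted by Newton–Raphson on the
log-likelihood aggregated over unique scores (identical likelihood to the
patient-level Bernoulli form, ~9 design rows for the reference data).
Numerical choices: intercept started at the logit of the observed
prevalence and slope at 0; monotone ascent enforced by step-halving;
convergence when the log-likelihood change is below 1e-10, capped at 100
iterations (the reference fit converges in 4). Complete separation is
detected up front (all deceased scores strictly above all alive scores,
or vice versa) and also via coefficient divergence (|β₁| > 30), raising
an explicit error — no Firth-type correction is attempted. The covariance
is the inverse observed information at the optimum.

Derived statistics:

* whole-model LR χ² = 2(ℓ_full − ℓ_null), df = 1, upper-tail p;
* per-unit odds ratio `e^{β₁}` with a Wald interval on the log scale;
* C-index by count arithmetic over per-score tallies (equal, and
  property-tested equal, to O(n²) pair enumeration; ties credited ½),
  with a Hanley–McNeil standard error for its interval;
* fitted probabilities at each observed score.

The score equation of ML logistic fits (Σ fitted probabilities = number
of deaths) is used as a test invariant, not assumed.

## Threshold analysis and classification rules

The scan runs from the maximum observed score down to 0 in the
deceased-positive orientation. The cut-point is the argmax of
sensitivity − (1 − specificity), with ties broken toward the higher
(more specific) threshold; no tie occurs in the reference data, so the
tie rule is unconstrained by it.

Two classification rules co-exist deliberately:

* **Score rule** `s ≥ T` — drives the scan and the dichotomized model.
* **Probability rule** `Pr(death | s) > 0.5` on the fitted model — drives
  the headline confusion matrix, reported in the alive-positive
  orientation some published ledgers use (survival as the "positive"
  prognosis). On the reference cohort only scores 7–8 have fitted
  probability above one half, so 7 patients are predicted deceased,
  giving the 183/73/3/4 matrix. With a monotone fit this rule is
  equivalent to a score threshold at the smallest score whose fitted
  probability exceeds the cut (property-tested).

Orientation is explicit on every matrix; internal computation is
deceased-positive, and the relabelled view is produced by a 180° cell
rotation. Under that relabelling sensitivity↔specificity, PPV↔NPV and
LR+ ↔ 1/LR−, while the cross-product odds ratio `ad/bc` is algebraically
invariant — the identities actually property-tested.

The dichotomized model's χ² is the LR statistic of the logistic model on
the binary indicator; since that model is saturated, the statistic is
computed in closed form from the 2×2 cells (`Σ_g [d ln(d/n) +
(n−d) ln(1−d/n)]` against the pooled null, with `0·ln 0 = 0`), which
agrees with the Newton fit and remains defined when a cell is empty.

## Metric ledger and interval methods

All ledger formulas act directly on the oriented cells a/b/c/d and
margins r1/r2/c1/c2/t: e.g. sensitivity a/c1, PPV a/r1,
LR+ = sens/(1 − spec), OR = (a/b)/(c/d), RR = (a/r1)/(c/r2),
DOR = [sens/(1 − sens)]/[(1 − spec)/spec] (algebraically the
cross-product OR), error odds ratio =
[sens/(1 − sens)]/[spec/(1 − spec)], Youden J = sens + spec − 1,
NND = 1/J, NNM = 1/(1 − accuracy), NNT = 1/|difference in proportions|,
κ = (p_o − p_e)/(1 − p_e) with chance agreement from margin products.
Metrics with zero denominators are reported as non-finite with a reason
code ("+inf"/"undefined" in JSON), never dropped.

Point estimates are the scientific content; interval methods are this
package's own choices, selected for good small-cell behaviour:

* Wilson score for all simple proportions (coverage within 2% of nominal
  at n = 263, p = 0.3 by simulation);
* log-scale delta method for OR, RR and both likelihood ratios, with the
  Haldane–Anscombe 0.5 correction applied to all four cells — interval
  only, flagged in the output — when a required cell is zero;
* Wald delta for Youden J and the difference in proportions;
* the large-sample SE `sqrt(p_o(1 − p_o)/(n(1 − p_e)²))` for κ;
* reciprocal measures (NNT/NND/NNM) by inverting the parent interval;
  when the parent interval crosses zero the corresponding bound is
  reported as infinite ("to infinite" in the Markdown view).

Display rounding follows the reporting convention of this literature
(3 decimals for proportion-type metrics, 2 for ratios, percentages in
parentheses); JSON keeps full precision.

## Bootstrap internal validation

Unstratified case resampling: each of the 1,000 cycles draws n records
with replacement, refits the model, and records the LR χ²; the report is
the empirical 2.5th–97.5th percentile interval. Resamples that cannot be
fitted (single outcome class, separation) are excluded and counted —
never replaced by zeros — with a warning above 10% failures and an error
at 100%. All randomness flows from the caller's seed through one
`numpy` generator; identical inputs give identical output. The interval
is a plain percentile interval (no BCa), matching the plain "CI range"
this procedure is meant to report. Across 100 independent seeds on the
reference cohort the observed χ² fell inside the interval every time;
note that the per-seed lower endpoint — a 2.5th-percentile estimate of a
right-skewed distribution — is itself highly variable, so stability
checks aggregate endpoints across seeds rather than constraining single
seeds.

## Synthetic cohorts

The generator draws scores i.i.d. from a categorical distribution over
0..S_max and outcomes from the logistic link — exactly the frame under
which the prognostic model is correctly specified. The distribution is
categorical rather than parametric because empirical MEWS frequencies
are irregular; `reference_spec()` uses the reconstructed reference
frequencies (mass on 0–8, mode at score 1) with the reference ML link
(β₀ ≈ −1.463, β₁ ≈ 0.217, ~29% mortality at n = 263) as the realistic
template. Vitals synthesis decomposes each target score into
per-component points (lexicographically smallest achievable vector,
components in sorted-name order with AVPU last) and emits the midpoint
of the first band worth those points — deterministic by construction.

What the generator does **not** emulate: correlated vitals, repeated
measurements per patient, deterioration trajectories, measurement error
in the score, or any miscalibration of the logistic link. Passing
parameter-recovery tests therefore demonstrates the estimation pipeline
is correct under its own assumptions, not that real escalation cohorts
follow a logistic link.

## Problem sizes used in tests

The test suite and analysis drivers run at the sizes the questions
demand: the reference cohort (n = 263) everywhere it is the subject;
1,000 bootstrap cycles (10 seeds for stability checks); 200 replicates
at n = 263 for the OR sampling-distribution check; n = 50,000 (20 seeds)
for parameter recovery; n = 100,000 for link convergence; 10,000
binomial replicates for Wilson coverage. The whole suite completes in
well under a minute on one CPU.

## Known limitations

* Interval methods are deliberately standard rather than exact; none of
  the printed intervals of the source evaluation are reproduced
  guarantees (its CI methods are unstated), only point estimates are.
* The dichotomized-model OR/RR intervals use the same log-delta
  machinery as the ledger; exact (conditional) intervals are out of
  scope.
* Reconstruction assumes one score per admission; repeated bedside
  measurements are out of scope.
* The error-odds-ratio formula is implemented exactly as its ledger
  definition; on matrices with near-zero cells it is numerically huge
  and its delta interval correspondingly unstable.
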