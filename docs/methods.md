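# Methods

## Setting and estimand

The package models a new-user, active-comparator cohort: incident statin
users classified at the index dispensation as high potency (≥ 10 mg
rosuvastatin, ≥ 20 mg atorvastatin or ≥ 40 mg simvastatin) or lower
potency, followed 730 days for incident diabetes (antidiabetic
dispensation, ATC A10, or a diabetes diagnosis, ICD-9 250.x / ICD-10
E10.x–E14.x). Eligibility requires a 365-day statin-free washout, a year
of coverage, age ≥ 40 and entry 1998–2010; lookback dispensation of other
lipid-lowering or antidiabetic drugs, a lookback diabetes diagnosis,
long-term-care admission, or more than one index statin excludes a
patient. Rules run in a fixed order and each excluded patient is counted
under the first rule failed, so the flow chart is deterministic and
conserves counts. The effect measure is the unadjusted odds ratio of the
outcome, high vs lower potency, in the full cohort and within each
matched sub-cohort ("no adjustment beyond matching"); with a conditional
null effect the marginal null is the truth in the matched samples, which
is what the coverage checks exercise.

## Score models

Both scores are unpenalized maximum-likelihood logistic regressions
(statsmodels Newton behind a scikit-learn-style estimator). Convergence is
declared on the parameter change (tol 1e-8, ≤ 100 iterations); after a
converged fit the score equation — mean fitted probability equals the
exposed fraction — is asserted to 1e-6. Constant and collinear columns are
dropped with a warning (small simulated cohorts produce empty strata);
perfect separation raises an error that names the offending column and
advises trimming or simplifying. Age enters linearly (the benchmark tables
summarize age as mean/SD, not categories); entry year enters as indicator
variables with the earliest observed year as reference.

The hdPS engine follows the standard empirical-covariate algorithm:

1. **Dimensions.** Lookback events (days 1–365 before entry) are counted
   per patient × code within six dimensions.
2. **Prevalence screen.** Per dimension the top 200 codes by
   min(p, 1−p), p the fraction of patients with ≥ 1 occurrence; codes with
   p ∈ {0, 1} carry no information and are excluded; ties break on the
   code string. (Raw-count ranking is available by option.)
3. **Recurrence expansion.** Per code, indicators for count ≥ 1,
   ≥ median and ≥ 75th percentile (nearest-rank quantiles over patients
   with ≥ 1 occurrence, deterministic on integer counts); indicators with
   equal thresholds collapse, and the selection quota counts distinct
   columns after the collapse.
4. **Bias ranking.** Candidates are ordered by |log bias| of the Bross
   multiplier computed from PC₁, PC₀ and the crude outcome risk ratio
   (inverted to ≥ 1). A zero margin in the candidate-by-outcome table
   makes the risk ratio undefined; such candidates score 0 (never
   preferred over informative ones) rather than receiving a continuity
   correction — the correction is available by option. Ties break on
   (dimension, code, recurrence level). The ranking is validated against a
   brute-force enumeration oracle in the tests.
5. **Design.** The top 500 empirical covariates join the forced set —
   sex, age, poverty, entry-year indicators and the three utilization
   flags; clinical investigator covariates are deliberately absent. An
   empirical column colliding with a forced name is suffixed, not merged.

## Trimming and matching

Trimming retains scores in [max of group minima, min of group maxima],
boundary inclusive, and errors when the groups are disjoint. The caliper
is 0.2 × the pooled sample SD (n−1) of the logit scores over both groups
after trimming (the SD population is configurable). High-potency patients
are processed in descending logit order (hardest to match first; ties by
patient id; random order with a seed is available), each matched without
replacement to the nearest remaining lower-potency logit; the pair is kept
only if the distance is within the caliper, and equidistant controls
tie-break on the lower id, making the whole procedure deterministic. When
every logit is identical the caliper degenerates to exact matching and a
warning is emitted. The implementation (sorted pool + bisection) is
checked against a hand-enumerated greedy oracle on small fixtures.

## Balance and effects

ASDD for a binary covariate: |p₁ − p₂| / sqrt((p₁(1−p₁) + p₂(1−p₂))/2);
for age: |m₁ − m₂| / sqrt((s₁² + s₂²)/2). Both are symmetric in the
groups and scale-free; a zero pooled variance returns 0 when the summaries
agree and +inf otherwise. Report rounding is 3 decimals, half away from
zero, matching the benchmark tables; a row is flagged unbalanced when
ASDD > 0.1 strictly. Odds ratios use the 2×2 cross-product with a Wald
95% CI; any zero cell triggers the Haldane–Anscombe +0.5 correction,
flagged on the estimate. Wald (rather than profile-likelihood) intervals
are a documented choice. A pair-stratified (conditional) estimate is out
of scope; the matched analysis is the unconditional 2×2 by design.

## Synthetic claims generator

One standard-normal latent frailty per patient captures general illness
severity. Baseline flags are independent Bernoulli given frailty
(log-odds 0.6 per frailty SD), with intercepts calibrated by bisection so
each flag hits its configured marginal prevalence (defaults: the
lower-potency column of the benchmark baseline table; poverty 0.35 and
acetaminophen 0.30 are not printed there and are set to plausible values
for a publicly insured population aged 40+). Age is truncated normal
(mean 65.2, SD 11.0, minimum 40) and standardized per 10 years inside the
models; entry year is uniform on 1998–2010 and kept categorical.

Treatment (high-potency initiation) is logistic in the flags and
standardized age, with coefficients backed out of the marginal
covariate-by-potency odds ratios of the benchmark baseline table (e.g.
PCI 1.33, MI 0.96, ≥1 hospitalisation 0.52, ≥5 visits −0.37 on the
log-odds scale), so the default full cohort reproduces imbalance of the
benchmark's magnitude. The outcome is logistic in the same flags
(moderate clinical risk-factor effects, ORs ~1.1–1.5), standardized age
and the treatment term, whose coefficient is the configurable true
conditional log OR (default 0). Both intercepts are calibrated by
bisection to the marginal targets (34.4% exposed, 3.2% outcome) to within
1e-6. Direct frailty effects on treatment and outcome default to zero —
all default confounding is through measured covariates, giving a known
truth — and can be switched on to emulate unmeasured confounding.

Lookback codes come in three kinds per dimension. *Definitional* codes
mirror how claims-derived covariates are constructed in practice: each
drug-dispensation flag has a code in the outpatient-drug dimension, each
diagnosis flag in the claim-diagnosis dimension and each
revascularisation in the inpatient-procedure dimension, occurring with
sensitivity 0.98 and false-positive rate 0.002 given the flag. *Proxy*
codes have a random sensitivity (0.3–0.9) and specificity noise
(false-positive rate 0.002–0.02) for a parent covariate assigned cyclically.
*Noise* codes occur at log-uniform base rates (0.01–0.25) independent of
everything. `code_confounder_loading` (default 0.9) interpolates every
parent effect between pure noise (0) and the full sensitivity (1), and
scales a mild frailty modulation (0.8 × loading per frailty SD) on all
loaded codes. Counts given occurrence are geometric on {1, 2, ...}
(success 0.55), producing the skewed once/sporadic/frequent recurrence
profile the expansion step assumes; event days are uniform on the
lookback window. The calibration of the code channel matters: the hdPS
can only balance what the codes can predict, and with definitional codes
present it balances the clinical flags nearly as well as the PS that
observes them directly — the regime the benchmark study operates in.
Index dispensations (product and dose consistent with the assigned arm)
are written at day 0; outcome cases receive an antidiabetic dispensation
or a diabetes diagnosis uniformly in days 1–730. All draws come from one
seeded stream in a fixed, documented order, so a seed determines the
dataset byte for byte.

What the generator does *not* emulate: real code vocabularies and their
frequency distributions, correlated covariate blocks beyond the single
frailty factor, time trends in prescribing, censoring or death during
follow-up (complete two-year observability is assumed), and the sheer
dimensionality of real claims (thousands of codes per dimension).
Passing tests therefore show the algorithmic machinery is correct and
that the method recovers a known truth under realistic imbalance — not
that hdPS dominates PS on any particular real dataset.

## Problem sizes and numerical conventions

The replicated null-recovery experiment uses 100 replicates at
n = 20,000 with 20 codes per dimension (~350 candidate covariates after
expansion) — large enough that matched CIs are informative, small enough
that the whole suite runs in a few minutes. Single-run balance checks use
n = 50,000. The benchmark-table checks are exact arithmetic on printed
counts; age rows are validated by interval arithmetic over the printed
rounding (means and SDs printed to one decimal constrain the ASDD to an
interval, and the published value must fall inside it). Intercept
calibration brackets by doubling and bisects to |mean − target| < 1e-9.
Bisection, sorting and tie-break rules are all deterministic; reruns with
the same seed produce byte-identical CSV output.

## Known limitations

- Covariate flags in raw (non-synthetic) claims are derived via a
  user-supplied code map; without flags or a map they are zero-filled
  with a warning.
- Patients with under two years of potential follow-up are not handled
  specially; complete observability is assumed.
- The hdPS tie-break and zero-cell conventions are documented choices,
  not claims about any particular legacy implementation.
- The comparison of PS vs hdPS balance is scenario-dependent; the
  pipeline reports both but asserts no ordering between them.
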