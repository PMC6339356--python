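# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind katascore, including what the synthetic cohort
generator does and does not emulate.

## The score

The modified Katagiri score sums six component points (primary growth
class 0/2/3, visceral status 0/1/2, laboratory category 0/1/2, ECOG 0/1,
prior chemotherapy 0/1, skeletal multiplicity 0/1) into a total of 0–10,
stratified 0–3 / 4–6 / 7–10 into low / intermediate / high risk. Two
rules deserve comment:

- **Corrected calcium.** The calcium threshold (≥ 10.3 mg/dL) is compared
  after albumin correction. The correction formula in routine use in the
  source setting is Payne's: `corrected = measured + 0.8 × (4.0 − albumin)`,
  applied only when albumin < 4.0 g/dL so the corrected value is never
  below the measured one. This choice is conservative for the critical
  threshold. With albumin missing the measured value is compared
  uncorrected and flagged.
- **Laboratory validity window.** Laboratory data are eligible when drawn
  within two months before the start of radiotherapy; we implement this as
  `[rt_start − 61 days, rt_start]`, treating older or future-dated values
  as missing.
- **Tier precedence.** A panel crossing both a critical-tier and an
  abnormal-tier threshold is *critical*: worst-tier dominance is the only
  reading monotone in the point values.
- **Missingness semantics.** A panel with no crossing but at least one
  missing analyte is *undetermined* — normality cannot be verified — and
  any unresolved component makes the patient non-scorable. Non-scorable
  patients are excluded from score-based analyses only (listwise per
  analysis elsewhere). Whether the original analysis treated
  no-crossing-but-incomplete panels as normal is not documented; we chose
  the stricter reading.
- **Unlisted primary sites** raise an explicit classification error;
  mapping a site to `other` (moderate growth) is a deliberate caller
  decision. The site vocabulary ships as an editable TSV. Age and KPS are
  analysis covariates only and carry no score points.

## Survival machinery

Implemented from first principles (the external lifelines package is used
in the test suite as an independent oracle only):

- **Kaplan–Meier**: product-limit over distinct death times; a censored
  observation tied with a death remains in that death's risk set. The step
  function is refused (NaN) beyond the last observed time. Median:
  smallest death time with S(t) ≤ 0.5 (inclusive), "not reached"
  otherwise.
- **Log-rank**: k-sample hypergeometric observed-minus-expected with the
  usual covariance; the statistic uses a pseudo-inverse on the first k−1
  coordinates (robust to degenerate risk sets) and is referred to
  chi-square with k−1 df. Zero total deaths → statistic 0, p = 1.
- **Cox proportional hazards**: Newton–Raphson on the log partial
  likelihood, Breslow tie handling by default (matching the default of
  mainstream commercial packages), Efron behind a switch. Risk-set sums
  are computed by cumulative sums over descending times (O(np²) per
  evaluation). Step-halving guards genuine likelihood decreases; decreases
  within 64 ulp of the current likelihood are treated as floating-point
  noise so late iterations can keep shrinking the score. Convergence:
  relative likelihood change < 1e-9 together with either score norm
  < 1e-8 or a Newton decrement below 1e-12 (the attainable further
  likelihood gain; this handles large samples where the likelihood
  plateaus first), followed by one polishing Newton step. Maximum 50
  iterations. Wald standard errors from the inverse observed information;
  95% CIs as exp(β ± 1.96·SE). Monotone likelihood (|β| drifting past 20)
  is flagged as suspected separation, never returned silently; rank
  deficiency is rejected at construction.
- Time is continuous months; display tables round medians to integer
  months and percentages to one decimal (the exact values are retained in
  `report.json`). Whether the original tables rounded or floored is
  unstated; we round and keep the exact values alongside.

## Validation pipeline

Factors: sex; age ≤64/≥65; KPS 10–60/70–80/90–100; ECOG 0–2/3–4; primary
lesion lung/breast/prostate/others; growth class; visceral status; lab
category; prior chemotherapy; multiplicity; risk group. Patients
unmappable for a factor are excluded from that factor's analysis only.

The multivariate specification fits **two canonical models** — one with
ECOG (no sex), one with sex (no ECOG) — plus a combined model marked
non-canonical. The published analysis states that sex and ECOG were
analysed separately without fully specifying the two designs; fitting both
and the combination surfaces the ambiguity instead of hiding it.
Reference levels (woman, KPS 90–100, ECOG 3–4, critical labs, rapid
growth, disseminated spread) report HR 1.000 with no interval. Previous
chemotherapy is configurable as a covariate but not part of the canonical
specification, since the published multivariate table omits it. No
multiple-testing correction is applied (none was applied in the source
analysis); the report footer counts the tests performed.

## Synthetic cohort generator

Real patient-level data are unavailable, so the generator emulates the
published *marginal* structure:

- **Survival.** Each risk group's event times follow a piecewise-
  exponential distribution with knots at 3/6/12/24 months. Segment hazards
  are solved in closed form, `h_i = ln(S(t_{i−1})/S(t_i))/(t_i − t_{i−1})`,
  so the implied survival reproduces the published group percentages
  (94.4/77.8/61.1/55.6, 67.7/48.7/31.2/16.0, 39.1/22.1/9.0/3.0) to machine
  precision at every knot. This is the simplest family that matches the
  reported values exactly; any smoother family would be under-determined.
  The low-risk tail hazard is calibrated so the analytic median equals
  27 months (S(24) = 55.6% leaves the median unconstrained by the profile
  alone); other groups continue the last segment's hazard. The implied
  analytic medians of the intermediate and high groups, 5.76 and 2.21
  months, round to the published 6 and 2.
- **Covariates.** Replica modes draw the published group sizes
  (18/133/205), sample a component-score combination uniformly among the
  3·3·3·2·2·2 = 216 combinations compatible with each group, and decode it
  into concrete covariate values (a site of the right growth class,
  analyte values realising the intended lab tier, an ECOG value in the
  right band, …) that re-score exactly to the intended group. Sex, age and
  KPS are drawn at the published validation-cohort frequencies.
- **Censoring.** Administrative: a per-patient horizon uniform on 24–137
  months, independent of the event time. This reproduces plausible
  survivor fractions without modelling accrual; it implies no censoring
  before 24 months.
- **Non-scorable patients** (`replica_entire` mode) extend the cohort to
  616 with 244 patients missing the laboratory panel and 16 missing
  visceral status — the counts implied by the published per-factor
  denominators — with event times drawn from the entire-cohort profile
  (57.7/40.5/23.4/12.2%).
- **`covariate_effect` mode** draws covariates independently at the
  validation-cohort frequencies and event times from an exponential
  proportional-hazards model with the published multivariate hazard ratios
  (man 0.479; KPS 10–60 1.796, 70–80 1.479; ECOG 0–2 0.690; labs normal
  0.312, abnormal 0.697; growth slow 0.278, moderate 0.708; visceral none
  0.428, nodular 0.753) on a baseline with median 2 months for the
  all-reference patient. This mode exists for parameter-recovery studies.

**What the generator does not emulate.** The joint covariate distribution
within risk groups is unpublished; uniform decoding over compatible score
combinations is a stand-in, so component-level marginals inside each group
(and correlations such as KPS with ECOG) do not match any real cohort.
Accrual, calendar time, treatment effects of RT schedules, time-varying
covariates and informative censoring are all absent. Passing tests on
these cohorts therefore demonstrate the *correctness of the pipeline's
arithmetic and its statistical calibration under the stated conditions*,
not the clinical validity of the score on new data.

## Problem sizes and tolerances in the test suite

Chosen to make sampling error negligible relative to each check: 50,000
uncensored draws for the generator round-trip (KM at 12 months within
3·√(p(1−p)/n) of the calibrated 9.0%); 20,000 patients for hazard-ratio
recovery (fitted log-HR within 3 SE of the generating value); 400
replicates for the log-rank type-I-error calibration (rejection rate at
α = 0.05 within 3 binomial SEs of 5%); 2,000–10,000 for the Cox null and
effect-recovery examples. Calibration identities are asserted at relative
tolerance 1e-12; cross-checks against the independent survival library at
1e-4 to 1e-12 depending on whether the quantity is closed-form or
iteratively fitted. End-to-end determinism is asserted byte-for-byte on
the report files under a fixed seed.

## Known limitations

- The albumin-correction formula used by the original analysts is not
  documented; Payne is an assumption (flagged above).
- The Breslow/Efron choice matters only under heavy ties; replica cohorts
  have continuous times where both coincide.
- The log-rank pseudo-inverse makes degenerate group configurations
  return a conservative statistic rather than an error.
- Score-based and non-score analyses share the scorable-cohort
  denominator in the replica pipeline; the published per-factor
  denominators are not all mutually consistent, and no attempt is made to
  reproduce their inconsistencies.
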