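# Methods

## Problem and scope

`bmidecomp` analyses change in women's body-mass index (BMI) categories
across repeated cross-sectional household surveys of the DHS type.  Two
kinds of quantity are produced:

1. **Survey-weighted trend metrics** — WHO band prevalences (underweight
   BMI < 18.5, normal [18.5, 25), overweight [25, 30), obese ≥ 30 kg/m²,
   plus the merged overweight ≥ 25 view), weighted mean BMI with linearized
   standard errors, percentage-point (ppt) differences between rounds, and
   the underweight:overweight prevalence ratio used as a double-burden
   progress proxy.
2. **A logit-scale multivariate decomposition** of the change in a binary
   outcome (underweight vs. others, or merged overweight vs. others)
   between an earlier wave B and a later wave A, into a
   characteristics/endowment component E (composition shift) and a
   coefficients/behavioral component C (effect shift), overall and per
   covariate.

The analysis population excludes pregnant women, women within the
puerperium, and women with unmeasured BMI, since BMI is not a meaningful
nutritional indicator in pregnancy or immediately postpartum.

## The decomposition model

Each wave's outcome is modelled by a weighted logistic regression on
dummy-coded categorical covariates.  On the logit scale the gap decomposes
as

    logit(A) − logit(B) = [β0A − β0B] + Σ βA (X̄A − X̄B) + Σ X̄B (βA − βB),

with X̄ the weighted category proportions.  Because the link is nonlinear,
the package reports components on the probability scale using
sample-averaged logistic evaluations rather than F applied to mean
covariates:

    D = p̄A − p̄B
    E = meanW_A[F(x'β̂A)] − meanW_B[F(x'β̂A)]
    C = meanW_B[F(x'β̂A)] − meanW_B[F(x'β̂B)]

where `meanW_G` averages over wave G's records with its sampling weights
and F is the logistic function.  Each converged fit satisfies its intercept
score equation (weighted mean fitted probability = weighted outcome mean),
so the telescope collapses and E + C = D holds essentially exactly; this is
the standard resolution for nonlinear decompositions, and it is asserted at
1e-10 on every run.

**Index convention.**  A is the later survey, B the earlier; D = late −
early, so a falling underweight prevalence has D < 0 (percentage
attributions are sign-free ratios to D, so a table printed with positive
magnitudes is recoverable).  The default counterfactual weights
characteristics by late-wave coefficients and coefficients by early-wave
characteristics, matching the equation above; the mirror-image
(`index="early"`) weighting is available because Oaxaca-type splits are
index-dependent.

**Detailed decomposition.**  Per-column contributions use Yun's
proportional weights built from the linear-predictor terms
s_E,k = βA,k (X̄A,k − X̄B,k) and s_C,k = X̄B,k (βA,k − βB,k); the intercept
(ΔX̄ = 0, X̄ ≡ 1) contributes to C only.  Components are apportioned as
E_k = E · s_E,k / Σ s_E.  If a component is non-negligible while its shares
sum to ~0 (|Σs| < 1e-12), the attribution is reported as undefined rather
than exploded.

**Categorical normalization.**  By default each covariate's coefficients
(including the reference's implicit 0) are re-expressed as deviations from
their unweighted mean over the categories, with the means folded into the
intercept.  The linear predictor of every record is unchanged, but detailed
contributions become invariant to the arbitrary reference-category choice
(asserted at 1e-6 under recoding).  Raw reference coding remains available
(`normalize=False`) since it is not knowable in general which convention a
given published table used.

## Estimation

Weighted logits are fitted by iteratively reweighted least squares (Newton
scoring) with step-halving, converging when the max-norm of the weighted
score falls below `tol` (default 1e-8) within `max_iter` (default 100)
iterations.  Numerical choices:

- Step acceptance tolerates log-likelihood changes within float noise of
  the accumulated deviance (1e-10·(1+|ll|)); otherwise step-halving stalls
  at large n where true improvements near the optimum are below rounding.
- After convergence up to two extra Newton "polish" steps drive the score
  to machine precision, so score-equation identities hold far below the
  reporting tolerances even on tiny toy datasets.
- Sampling weights are frequency-style weights in the likelihood: point
  estimates equal design-weighted estimates, and all estimates are
  invariant to rescaling the weights by a positive constant (asserted).
  Design-based uncertainty is delegated to the bootstrap.
- |β| > 15 with no genuine likelihood progress is treated as
  complete/quasi-complete separation and raised as an error naming the
  covariate (on the logit scale 15 corresponds to risks ~3e-7, far outside
  anything estimable from survey data); a small optional ridge penalty is
  available behind a flag rather than applied silently.
- Rank deficiency is detected up front by pivoted QR on the
  weight-scaled design and reported with the collinear column names.
- The coefficient covariance is the inverse weighted observed information.

## Uncertainty

Confidence intervals come from a seeded percentile bootstrap (default 500
replicates), resampling whole clusters with replacement within each wave
when cluster identifiers are present (two-stage-design flavour), records
otherwise.  Replicates that fail to converge are redrawn and counted; more
than 10% failures aborts the run.  A delta-method variance is a known
non-goal.  Percentage attributions are suppressed when |D| < 1e-4 to avoid
explosive ratios.

The trend module also offers a design-naive two-sample weighted-proportion
z-test (Kish effective sample sizes); it ignores clustering, will overstate
precision on clustered designs, and is labelled accordingly — the test
actually used for published trend p-values in this literature is typically
unstated.

## Synthetic cohorts and the oracle

The generator emulates the statistical skeleton of a DHS wave: fully
categorical covariates drawn independently from wave-specific marginal
compositions (a joint cell table can be supplied for correlated
covariates); a Bernoulli outcome from wave-specific logit coefficients;
unit-mean gamma(4, 0.25) individual sampling weights; 600 enumeration-area
clusters with equal allocation and an optional logit-scale cluster random
intercept (off by default); pregnancy/puerperium/missing-BMI flags at rates
8%/8%/4%; and a BMI drawn uniformly from the band implied by the generated
outcome so that classification and dichotomization round-trip.  One integer
seed feeds one named RNG stream per wave.

It does **not** emulate: probability-proportional-to-size EA selection or
household listing, informative weights (weights are independent of
covariates and outcome), real BMI distributions within bands, covariate
correlation (in the shipped presets), item nonresponse beyond the missing-
BMI flag, or time trends within a wave.  Passing tests therefore show that
the estimator recovers a correctly specified data-generating process at
survey scale — not that any particular published estimate is right.

`population_truth` computes D, E, C exactly by enumerating the joint
covariate cells (no sampling, no fitting), and apportions them with the
same Yun weights on normalized true coefficients.  Four presets ship, with
compositions and outcome margins calibrated to the published Ethiopian DHS
respondent tables (education expansion, urbanisation, contraceptive uptake;
underweight 31.25% → 23.18%, merged overweight 3.49% → 7.74% nationally):

- `composition_shift_only` — identical coefficients, so true C = 0;
- `coefficient_shift_only` — identical compositions, so true E = 0;
- `mixed_underweight_decline` — both shift, true D ≈ −8.1 ppt;
- `urban_overweight_rise` — merged-overweight outcome, true D ≈ +4.2 ppt.

## Problem sizes used by the tests

Parameter-recovery acceptance runs use the presets' default n = 50,000 per
wave over 20 seeds per preset, comparing seed-mean estimates with the
oracle at 3 Monte-Carlo standard errors.  The coefficient-coverage smoke
test uses 40 replicates at n = 50,000 with equal weights (reported
model-based SEs are only calibrated for non-informative equal weights; with
gamma weights the bootstrap is the calibrated uncertainty).  Bootstrap
coverage of the null C component is exercised at n = 5,000 per wave with
200 replicates over 10 seeded runs; unit tests use hand-built waves of a
few records or generated cohorts of 2,000–8,000.

## Known limitations

- Two waves only; sequential multi-wave decomposition is out of scope.
- Logit link only; no probit/cloglog, no continuous covariates or splines
  (the oracle is enumeration-based and requires finite categorical support).
- Exclusion tallies use a fixed precedence (pregnant → puerperal →
  unmeasured BMI) so reasons are disjoint; published cascades rarely state
  their precedence, so tallies may not match a given report line for line.
- The puerperium is operationalised as months-since-last-birth < 2 (DHS
  postpartum convention), configurable via `puerperium_months`.
- DHS-dialect CSV input covers the common conventions (BMI ×100 with
  ≥ 9990 sentinels, weight ×1e6); native .DTA/.SAV recode files are not
  read — export to CSV first.
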