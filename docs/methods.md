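# Methods

`cartpk` implements a population cellular-kinetic analysis of CAR T-cell
transgene concentrations (copies/µg genomic DNA measured by ddPCR in
peripheral blood) after a single infusion, together with the synthetic-cohort
machinery used to validate every stage against known ground truth.

## Structural model

Concentration follows exponential expansion into biexponential contraction:

```
rho  = ln(foldx) / t_max
f(t) = (c_max/foldx) · exp(rho·t)                                   t <  t_max
f(t) = c_max · [(1-fb)·exp(-alpha·(t-t_max)) + fb·exp(-beta·(t-t_max))]   t >= t_max
```

with six parameters: peak concentration `c_max` (copies/µg), peak time
`t_max` (days), fold-expansion `foldx` (> 1, so the post-infusion baseline is
`c_max/foldx`), memory fraction `fb` ∈ (0,1), and contraction rate constants
`alpha > beta` (1/day).  Both branches equal `c_max` at `t_max`.  Derived
quantities: doubling time `ln2/rho`, fast and terminal half-lives
`ln2/alpha`, `ln2/beta`, and the closed-form AUC of the piecewise
exponentials.

The early post-infusion dip that real transgene curves show before expansion
is deliberately not modelled; the curve starts at `c_max/foldx` as written.

Two modifications are supported:

* **Extramedullary disease** multiplies `c_max` by a categorical factor
  `theta_EMM` (estimated 0.468 in the reference parameterization — patients
  with soft-tissue disease reach roughly half the peak).
* **CRS comedications**: from the first tocilizumab administration the
  expansion rate is multiplied by `F1`, from the first corticosteroid dose by
  `F2`, compounding when both are on board.  As printed, the contraction
  branch stays anchored at `c_max`, which leaves a discontinuity at `t_max`
  whenever `F1·F2 ≠ 1`; this verbatim behaviour is the default
  (`comed_anchor="as-published"`), with a `"continuous"` variant that anchors
  contraction at the value the expansion branch actually attained.  When
  steroids precede tocilizumab the multipliers engage in chronological
  order — a documented extension of the printed two-segment formula, which
  assumes tocilizumab first.

The effector/memory decomposition splits the curve into a fast compartment
`y_alpha` (grows at `rho`, then decays at `alpha`) and a persistent
compartment `y_beta` (zero through `t_max`, inflow `fb·(alpha-beta)·y_alpha`,
decay `beta`).  The sum reproduces the closed form; the package integrates
the ODEs numerically (RK45, rtol 1e-9, split exactly at `t_max`) and also
provides the analytic solution
`y_beta(t) = fb·c_max·(e^(-beta·tau) - e^(-alpha·tau))` as a cross-check.

## Population model and random effects

Between-subject variability is log-normal: `p_i = theta_p · exp(eta_p)`,
`eta ~ N(0, omega²)`, with the tabulated %CV mapped through
`omega² = ln(1 + (CV/100)²)`.  Because `fb` is a fraction, its eta acts on
the logit scale, `fb_i = expit(logit(fb) + eta)`; this agrees with
`fb·exp(eta)` to first order for small `fb` but keeps every realisation in
(0,1) and — critically — is smooth in `eta`.  (A hybrid rule that switches
from exponential to logit only when `fb·e^eta` exceeds 1 was rejected: the
switch is discontinuous in `eta`, and the conditional-mode search of the
estimator stalls on the resulting likelihood cliff.)  A pure exponential
scale remains available (`fb_eta_scale="exp"`).

Residual error is combined proportional + additive on the natural
concentration scale, `y = f·(1+eps_p) + eps_a`, with `sigma_prop` quoted in
percent and `sigma_add` in copies/µg; a log-scale alternative
(`error_scale="log"`) treats `ln y = ln f + eps` with variance
`sigma_prop² + (sigma_add/f)²`.  The tabulated magnitudes
(`sigma_prop = 47.01%`, `sigma_add = 0.319`) do not identify the
transformation; natural scale is the default and all reference validation
uses it.

Reference parameterization (the modified-model estimates):
`c_max 67,060`, `t_max 8.657 d`, `foldx 5,460`, `fb 0.1172`,
`alpha 0.1093 /d`, `beta 0.006122 /d`; BSV CVs 59.49 / 29.01 / 215.6 / 154 /
73.49 / 107.3 %; `theta_EMM 0.468`; comedication multipliers
`F1 0.966`, `F2 0.944`.

## Synthetic cohorts

`generate_cohort` emulates the 18-patient dose-escalation design: doses 1/3/6
×10⁶ CAR⁺ cells/kg allocated 9/6/3 by largest remainder; extramedullary
prevalence 5/18; prior murine CAR-T 4/18; prior auto-HSCT 6/18; tocilizumab
11/18 and corticosteroids 12/18 with first-administration times uniform on
days 1–7 (CRS interventions cluster in the first week); visit schedule
days 0, 4, 7, 10, 14, 21, 28, 60, 90, 180, 270, 365 (the study's published
visit grid is not available; this emulates its density — dense through
expansion/peak, sparse to one year); quantitation limit 20 copies/µg with
BLQ records retained as censored rows.  At the reference parameterization
this yields ≈ 8–11% BLQ records, matching the study's 41/469.

Each subject owns four RNG substreams (covariates, etas, residuals,
comedication) spawned from the master seed, and covariate uniforms are drawn
in a fixed order, so changing one prevalence never reshuffles any other
subject's data.  Eta draws violating the structural ordering
(`beta_i ≥ alpha_i`, `foldx_i ≤ 1`; < 1% probability at the reference
magnitudes) are rejected and redrawn — a documented, negligible truncation.
Binary response labels default to Bernoulli(0.78), matching the observed
1-year remission proportion (14/18); the generator does not model
anti-drug antibodies, retreatment or dropout.

## Estimation (Laplace NLME)

Each subject's marginal likelihood integral over its etas is approximated at
the conditional mode: with `h(eta) = -2[log p(y|eta) + log p(eta)]`,

```
OFV_i = h(eta_hat) - k·ln(2π) + ln det H_i,     H_i = ∇² h(eta_hat) / 2 .
```

BLQ records contribute `-2·ln Φ((LOQ - f)/sqrt(v))` (M3); options discard
them or substitute LOQ/2.  Fixed effects are optimised on transformed scales
(log; logit for `fb`; `beta = alpha·expit(z)` to keep `beta < alpha`),
omegas and sigmas on the log scale, with a 1e-8 sigma floor and omegas
bounded below at 1e-3 (so "no variability" is represented by a practically
negligible 0.1% CV).

Numerics that matter:

* **Peak smoothing.** The branch switch at `t_max` makes the likelihood
  non-differentiable in the `t_max` eta wherever an observation time crosses
  the subject's peak, which stalls Newton iterations and leaves conditional
  modes pinned at kinks.  The estimator therefore evaluates the structural
  model with a narrow logistic blend of the two branches on the log scale
  (`peak_smooth_days = 0.1`); both branches equal `c_max` at the peak, so
  the blend deviates from the exact piecewise model only within ~±0.3 day of
  `t_max` (≲ 2% of `f` there, far below the 47% residual error).  Simulation
  and the public kinetics API always use the exact piecewise form.
* **Inner solver.** Modes for all subjects are found simultaneously:
  vectorised damped Gauss-Newton sweeps, then saddle-free full-Newton sweeps
  (finite-difference Hessians, eigenvalue magnitudes with a relative floor,
  each factorisation reused for a few steps), cycled until the per-subject
  Newton decrement falls below 1e-9, with a batched golden-section
  coordinate polish as a safety net.  Modes are warm-started between outer
  evaluations; the model/likelihood kernels are numba-compiled with a pure
  numpy fallback.
* **Outer optimiser.** L-BFGS-B with explicit finite-difference step 1e-4,
  re-invoked from its own solution (fresh quasi-Newton memory) while the OFV
  keeps improving, then a few seeded jitter restarts from the incumbent
  ("basin hops") because the profile likelihood forms a curved, nearly flat
  ridge in (c_max, foldx, fb, beta) with shallow local basins.  Initial
  estimates come from a naive two-stage stage: per-subject log-scale curve
  fits pooled by robust log-medians/MADs, with cross-subject heuristics as
  fallback.
* **Laplace Hessian.** `ln det H` uses central finite differences
  (step 1e-3) at the mode; a Gauss-Newton fallback covers non-positive
  definite cases.  `hessian="gauss-newton"` switches the whole objective to
  the first-order (FOCE-like) curvature.
* **Uncertainty.** Standard errors invert the finite-difference Hessian of
  OFV/2 in the transformed parameters and delta-map to the natural scale;
  reported as RSE%.  Eta shrinkage is `100·(1 - SD(EBE)/omega)` by default,
  with the variance-ratio convention (`1 - Var/omega²`) as an option.

Known limitations: the objective retains small evaluation noise (~1e-2)
from warm-started inner solves, so OFV differences below ~0.1 are not
meaningful; with 12 observations per subject and six large random effects,
per-subject conditional surfaces can be multimodal and the reported OFV
depends on the optimisation path at that order; and estimates at n ≈ 100
carry sampling error of roughly `omega/√n` (≈ 9–13% for `foldx` and `beta`),
so single-cohort recovery within 15% is expected but not guaranteed.

## Covariate analysis

Stepwise covariate modelling adds candidate covariate-parameter relations
(categorical fractional multipliers; power functions `(cov/median)^theta`
for continuous covariates, the reference value frozen with the model) by
forward inclusion at ΔOFV > 3.84 (χ²₁, p = 0.05) and backward elimination of
any term whose removal costs < 6.63 (χ²₁, p = 0.01); the largest significant
ΔOFV wins each forward pass, ties broken by declaration order, and every
candidate evaluation is recorded in a replayable trace.  Three safeguards
keep the ΔOFV comparisons honest on this multimodal likelihood: candidate
terms are initialised from the covariate's imprint on the base fit's
empirical-Bayes etas; an extended model is never allowed to score worse than
its nested base (with a neutral-start retry when the first refit does); and
before a winner is accepted the current model is refit from the winner's
shared parameters, so an OFV drop that merely reflects a better basin of the
shared parameters restarts the pass instead of being credited to the
covariate.  At very small cohort sizes (n ≈ 12) the χ²₁ reference for the
ΔOFV test is itself anti-conservative, so null inclusion rates above the
nominal level there reflect small-sample likelihood-ratio inflation rather
than a selection defect.  Descriptive
screens: Mann-Whitney U (Welch t optional — the tests behind the published
p-values are not named, so exact reproduction is not claimed) comparisons of
empirical-Bayes etas and of observed AUC over days 0–28 (linear trapezoid,
BLQ records at LOQ/2) across covariate levels.

## Diagnostics

The pcVPC simulates replicate datasets at the exact input design (times,
covariates, comedication schedules), bins records by time quantiles (8 bins
by default; edges configurable since the published binning is not stated),
prediction-corrects observed and simulated values by the bin-median typical
prediction, and reports the observed 2.5th/50th/97.5th percentiles with 90%
simulation envelopes.  Records whose observation is BLQ are excluded from
the percentile computation; simulated values below the LOQ enter uncensored.
CWRES uses the first-order-conditional linearisation at the EBEs
(`cov = G·Omega·G' + V`, central-difference Jacobians, step 1e-5) and is
approximately N(0,1) under the correct model.

## Secondary analyses

Exposure-response fits a logistic regression of binary response on dose
(numeric 10⁶ cells/kg by default, categorical optionally); a degenerate
outcome (e.g. 100% response at every dose, as seen at day 90) or complete
separation triggers an L2-penalised fallback with no trend p-value.
"Response" defaults to overall response; a CR-only endpoint is a caller-side
relabelling.  Clone analytics work on proportional abundances: major-clone
labelling at ≥ 3% abundance (top three ranked, remainder pooled as
low-abundant, totals conserved), Simpson's reciprocal index `1/Σp²`
(scale-invariant, so proportions vs read counts is immaterial), and
per-subject diversity trajectories.  The published "no salient drop"
statement is not quantified; the package flags a drop when any later index
falls below 0.2× the running maximum — a documented package choice.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate against simulated truth
at: parameter recovery n = 100 subjects × 12 visits; comedication-effect
recovery n = 100 on a 10-visit schedule that samples daily across the
comedication window (days 2–8) with low (5%) residual noise; stepwise-
covariate-model operating characteristics at n = 64 (effect present, power
for the 0.468 multiplier ≈ 0.99 at the 3.84 criterion)
and n = 12 (null, several replicates × 2 candidates) on a 10-visit
schedule; pcVPC calibration over 5 independent 18-subject cohorts with 250
simulation replicates each.  These sizes keep the whole validation to
roughly half an hour on one CPU while holding Monte-Carlo error small
relative to the tolerances checked; note that single-cohort recovery of
weakly identified parameters (`fb`, `beta`, `foldx`) carries ~9–13%
sampling error at n = 100, so individual draws can land outside a 15–20%
band even for a correct estimator.  Passing these checks demonstrates
internal consistency of simulator + estimator under the emulated design,
not performance on real clinical data, which additionally exhibits the
early dip, irregular visit times, dropout and assay artefacts that the
generator does not model.
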