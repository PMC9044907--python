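# Methods

This note documents the statistical model behind `prescore`, the synthetic
data it is validated on, the defaults and why they were chosen, and the
limitations a user should keep in mind.

## The risk model and the score

Marker–outcome associations are estimated on a *background* cohort — a
population independent of the trial being scored — with a multivariable Cox
proportional hazards model over eight modifiable risk markers: HbA1c (%),
systolic blood pressure (mmHg), UACR (mg/g, entered as its natural
logarithm because of its strong right skew), body weight (kg), hemoglobin
(g/L), HDL and LDL cholesterol (mmol/L), and serum potassium (mmol/L).
Partial-likelihood maximization (Efron tie handling) is delegated to
`lifelines`; the package computes the Breslow baseline cumulative hazard
H₀(t) itself, as an explicit step function, so that a fit serializes to
JSON and scoring never requires refitting.

The linear predictor is centred at the background-cohort means of the
transformed markers.  The reference level is not identified by the Cox
model itself; centring at the cohort mean makes `exp(lp)` a hazard relative
to the average background patient, keeps H₀ interpretable and bounds the
numerical range of `exp`.  Absolute risk by horizon t is
`1 − exp(−H₀(t)·e^lp)`, with no extrapolation beyond the last observed
event time.

Transferring the coefficients to a two-arm trial, each patient is scored at
baseline and at first follow-up; only the markers in the chosen subset are
updated to follow-up values (the rest enter at baseline twice), which
yields single-marker scores and the integrated score in one frame.  With
arm means R̄ and Δ_arm = (R̄_fu − R̄_bl)/R̄_bl, the reported estimate is

    RRR% = −100 · (Δ_treatment − Δ_placebo).

The phrase "adjusted for the placebo arm" is ambiguous between this
difference of relative changes and a ratio form
`100·(1 − (1+Δ_T)/(1+Δ_P))`; the difference form is the default and the
ratio form is available via `method="ratio"`.  Both are exactly zero under
the null (no between-arm difference in changes).  Two properties of the
difference form worth knowing:

* a change common to both arms cancels exactly only under the null;
  with a treatment effect present the cancellation is first-order (risk is
  nonlinear in the linear predictor), which the test suite demonstrates;
* because the denominator is the *baseline* mean risk while the numerator
  compares *follow-up* mean risks, within-person follow-up variability
  inflates the estimate slightly (Jensen's inequality on `e^lp`); with
  realistic within-person noise the bias is well under a percentage point
  on the scale of the headline estimates, and the end-to-end recovery test
  bounds it empirically.

The risk horizon defaults to 3.5 years (inside the follow-up of the trials
this emulates); under proportional hazards the RRR is a ratio of ratios and
nearly horizon-invariant, which is asserted as a property test.

## Uncertainty

The 95 % CI is a parametric percentile bootstrap: 100 coefficient vectors
(default, configurable) drawn componentwise from independent
Normal(β̂ᵢ, seᵢ), the RRR recomputed per draw with H₀ and the centring held
fixed.  Componentwise-independent draws are the documented convention of
the method; a multivariate-normal mode using the full estimated covariance
is available behind a flag and is statistically preferable when the
coefficients are correlated.  The interval therefore quantifies
**coefficient uncertainty only** — not trial sampling noise, not H₀
estimation error.  The bootstrap-calibration experiment in the test suite
is designed accordingly: coverage is assessed against the RRR implied by
the *true* generator coefficients on the same trial with the same fitted
H₀/centring, with the background cohort refit per replicate so coefficient
error is redrawn each time.  Coverage against a fixed population truth
would additionally require trial-level resampling, which the method does
not model; this is a known limitation, not a defect of the implementation.

## Multiple imputation

Follow-up markers can be missing (in the emulated trial, because some
markers are simply not measured at the 6-month visit).  Under a
missing-at-random assumption the package imputes with chained equations and
predictive mean matching: each incomplete variable is regressed (OLS, on
the transform scale) on all other marker columns plus the arm indicator;
coefficients are drawn from the approximate Bayesian posterior (normal
around the OLS fit, scaled inverse-chi-square residual variance); each
missing case receives the observed value of one of k = 5 donors nearest in
predicted mean (ties and the donor pick resolved by the seeded generator).
Variables are visited in increasing order of missingness; 5 sweeps; m = 5
completed datasets.  m, the sweep count and k are the common defaults of
chained-equation software; none is dictated by the method itself.  Pooling
across imputations averages the point estimates and pools the bootstrap
draws before taking percentiles — deliberately simpler than Rubin's rules,
which do not directly apply to a percentile interval on a nonlinear
functional; the mask-and-recover test bounds the end-to-end error of this
convention (±1.5 percentage points at 30 % missingness on two markers).

## Scenario simulation

A *responder* is a treated patient whose reduction (transform scale) is ≥
the treatment-arm median reduction; ties count as responders, so a
degenerate all-identical arm is all responders.  Enrichment resamples the
treatment arm with replacement within responder strata to hit a requested
responder proportion, preserving arm size and leaving placebo untouched —
resampling keeps n fixed and is seedable, which an analytic reweighting
would not be.  Rescoring across a proportion grid traces RRR against the
realized placebo-corrected change (reported for log markers as a percent
reduction `100·(1 − e^Δ)`), and linear interpolation of change against RRR
inverts the curve for a target, returning the smallest change that
achieves it.  One marker is enriched at a time; because follow-up noise is
independent across markers, enriching on one marker leaves the others'
contributions flat in expectation (tested).  Inclusion-criteria filtering
(conjunction of disjunction-groups over baseline columns) restricts a
trial to a narrower population first; the shipped CKD band (eGFR 25–60
ml/min/1.73 m², UACR 200–5000 mg/g) is an explicit stand-in assumption
selecting roughly 5 % of the default trial.

## The synthetic-data generator

Real patient-level data for this kind of analysis are not public, so the
package generates its own, with the generating truth exposed for
validation:

* **Baseline markers**: multivariate normal on the transform scale
  (Gaussian copula), marginals matching the published cohort tables —
  trial panel: HbA1c 8.7 (1.55) %, SBP 135.9 (17.75) mmHg, UACR median
  24.8 mg/g (log-SD 2.28), weight 91.75 (21) kg, Hb 137.1 (15) g/L, HDL
  1.2 (0.3), LDL 2.3 (0.9), K 4.5 (0.5) mmol/L; background panel with the
  markedly higher-risk profile (UACR median 276.9 mg/g, eGFR-poor
  population).  Marker correlations are not published; an exchangeable
  0.1 off-diagonal default is used and fully configurable.  Baseline eGFR
  is generated as an auxiliary covariate correlated −0.35 with log-UACR.
* **Event times**: proportional hazards with Weibull baseline (default
  shape 1 = exponential), linear predictor β_true·(z − μ), administrative
  censoring at 4 years plus exponential random censoring (0.02/yr).  The
  baseline rates are calibrated by Gauss–Hermite quadrature so the default
  background cohort reproduces composite event fractions of 17.8 %
  (kidney) and 12.5 % (CV), and the trial 2.5 % / 13.9 %.
* **True coefficients** (per transformed unit): kidney
  (0.03, 0.008, 0.90, 0.003, −0.010, −0.20, 0.04, 0.15), CV
  (0.027, 0.006, 0.20, 0.004, −0.006, −0.30, 0.10, 0.10) in panel order.
  Chosen once so that the implied effects sit in the published range for
  such scores — log-UACR dominant for the kidney outcome, glycemia and
  lipids relatively more important for CV — giving headline RRRs of
  roughly 14–16 % (kidney) and 7–9 % (CV) under the default shifts.
* **Treatment effect on markers** (placebo-corrected, at follow-up):
  HbA1c −1.4 %, SBP −3.0 mmHg, UACR −13.2 %, weight −2.3 kg, Hb −2.6 g/L,
  HDL +0.01 mmol/L, LDL and K unchanged.  Placebo drifts are small
  plausible values (HbA1c −0.2, SBP −0.5, weight −0.5, log-UACR +0.01);
  they are assumptions, not published quantities.
* **Follow-up noise**: within-person SDs per marker (HbA1c 0.7 %, SBP 9
  mmHg, log-UACR 0.45, weight 3 kg, Hb 7 g/L, HDL 0.12, LDL 0.35, K 0.3),
  reflecting short-term biological plus measurement variability.  Half the
  cross-sectional SD (the fallback when a marker specifies none) would be
  far too large for UACR and weight — three-fold UACR swings and ±10 kg —
  and would also materially inflate the estimator through the Jensen
  mechanism above.
* **Outcome generation in the trial** uses the *follow-up* linear
  predictor, so the between-arm effect is purely marker-mediated — the
  ground truth the score should recover, computed independently by
  brute-force counterfactual simulation (same patients, events simulated
  with and without the marker shifts, shared exponential draws).  A
  per-outcome `direct_effect` hazard multiplier adds a non-marker-mediated
  component; with a direct CV benefit configured, the score reproduces the
  characteristic pattern of matching the kidney effect while
  underestimating the CV effect.
* **Missingness**: per-marker follow-up rates (defaults 8–12 % on the
  markers measured late), MCAR or MAR (logistic in the standardized
  baseline value, intercept solved for the marginal rate).

What the generator does **not** emulate: real marker correlation
structure, longitudinal multi-visit trajectories, non-Gaussian marker
marginals other than log-UACR, informative (MNAR) missingness, competing
risks, or non-proportional hazards.  Passing tests therefore demonstrate
the machinery is correct under a faithful PH world, not that the score is
unbiased on any real dataset.

## Numerical choices and problem sizes

Seeds are explicit everywhere; every stage draws from streams spawned from
one configuration seed, and identical configurations reproduce outputs
byte-identically.  Quadrature calibration solves for the baseline rate on
a 101-node Hermite grid with Brent root-finding (tolerance 1e−12).  The
validation suite runs its heavy experiments at sizes chosen to make
Monte-Carlo error small relative to the tolerances asserted: coefficient
recovery at n = 20,000; end-to-end RRR recovery over 10 replicate
pipelines (trials 4,500/arm) against a 10⁶-patient counterfactual truth;
bootstrap calibration over 200 replicates (background 3,000, trials
500/arm); the full suite completes in about a minute on one core.

## Known limitations

* The CI ignores trial-level sampling noise (see *Uncertainty*); with
  heavy-tailed predicted risks (log-normal UACR with a strong
  coefficient), arm-mean risks are dominated by the upper tail and small
  trials scatter accordingly.
* The difference-form estimator carries the small Jensen inflation
  described above; the ratio form largely cancels it and is available for
  sensitivity analysis.
* Single-marker scores do not sum to the integrated score (risk is
  nonlinear); this is a feature of the method, asserted in the tests.
* The observed-outcome analysis of a real trial (fitting the trial's own
  event data) is out of scope; the "observed" effects quoted in
  validation are simulated ground truths.
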