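# Methods

## The model

Conception to an AI service is Bernoulli with probability

logit P(y=1) = β₀ + β_breed + β_age·age₁₀ + β_CIV·CIV + β_month +
γ_month·age₁₀ + u_g,  u_g ~ N(0, σ²),

where g indexes herd-years. The packaged generative parameter set
(`params/published_odds_ratios.yaml`) carries the published odds ratios: breed contrasts
against Friesian (FR), calving-interval PTA 0.93 per day, month contrasts
May 7.70 and June/July 146.98 against April, and age-by-month interaction
ratios 0.97 (May) and 0.92 (June/July) per 10 days of age; σ = 0.78. The
age main-effect ratio is printed as 1.00 per 10 d, so the generative age
main effect is exactly zero and only the interactions carry age
information; this insensitivity is intentional and documented.

Two scale conventions matter:

* **Generation** applies the published ratios with age in raw 10-day units
  (`age_center_days = 0`). This is the only reading under which the month
  and interaction ratios are jointly plausible: at a typical service age of
  460 d the implied June/July odds ratio is exp(ln 146.98 + 46·ln 0.92) ≈ 3,
  and May ≈ 1.8, consistent with May services being roughly 1.6× as likely
  to succeed as April ones. Taken at face value with centred age the month
  effects would be absurd (odds ×147).
* **Fitting** centres age at 460 d (`age10 = (age_days − 460)/10`) purely
  for numerical conditioning. Predictions are invariant to the centring
  constant (asserted by a test): the shift is absorbed by the month main
  effects.

No intercept is published. `calibrate_intercept` finds it by bisection so
that the Monte-Carlo marginal conception rate over the sampled covariate
and random-effect distribution hits a target (default 77.7%) within 0.005.

## Record cleaning

Rules are applied per animal-season (services of one heifer within one
calendar year, sorted by date), in a fixed order chosen so each rule sees
inputs satisfying its preconditions:

1. same-oestrus removal (gap < 3 d; first of a run retained; a recorded
   positive outcome transfers to the retained service — discarding it would
   corrupt the season outcome);
2. outcome assignment from the first non-abortion calving after the last
   service: gestation in [267, 300] confirms the final service (correcting
   a recorded negative, counted); gestation < 267 prefers the earlier
   service whose gestation is nearest 282 within [267, 300] (ties to the
   later service) and removes later services; gestation > 300 removes the
   final service and attributes no conception;
3. problem-season removal: ≥ 3 services with ≥ 2 inter-service gaps ≤ 10 d
   (the source text gives no quantitative rule; these three parameters are
   an explicit, configurable guess);
4. carryover removal: services outside April 1 – July 31 in seasons with no
   positive outcome;
5. renumbering of service numbers and inter-service intervals, then
   derivation of the month/interval/service-number categories.

Design choices worth noting. The over-long-gestation rule applies only when
the final service was recorded positive or unknown: a recorded-negative
final with an unexplained later calving is left alone, which is what makes
the pipeline idempotent (cleaning cleaned data is a no-op with an all-zero
audit — asserted by tests). A short-gestation final with no aligned earlier
service is kept positive unless explicitly recorded negative (premature
calvings exist). The 282 ± 15 correction window sits inside [267, 300], so
the correction is implemented as "recorded-negative final confirmed by a
calving in the valid window".

## Synthetic herds

The generator emulates the study structure: 12 herds (two research herds
with ten breeding seasons, ten commercial herds with four or five), per-herd
mean ages at service of ~440–537 d (SD 18–79), per-herd April–July service
mixes, a nine-category breed mix dominated by Holstein/Friesian, CIV PTA ~
N(0, 1.5 d), gestation 282 ± 4 d truncated to [270, 294], and return to
service after 21 ± 3 d (truncated ≥ 11 d so no natural season trips the
problem-season rule). A failed heifer is re-served with probability 0.85
per cycle until the window ends — oestrus re-detection is imperfect in
practice, and this leaves a realistic ~5% of seasons open; services per
animal-season land at ~1.26–1.37, within the reported 1.2–1.4. The herd-year
random intercept is drawn once per herd-year.

Defects are planted disjointly by animal-season so the ledger is an exact
oracle for the cleaning audit: duplicate services 1–2 d after a true
service; embryonic loss in two forms (an extra recorded-positive service
whose calving arrives > 300 d later, and a later presumptive service whose
implied gestation is < 267 d, planted on single-service conceiving seasons
so the true conceiver is unambiguously the best-aligned earlier service);
conceiving finals flipped to negative; autumn carryover services for open
heifers; whole problem seasons on fresh animals (four services with gaps of
4–10 d); and missing breed/CIV values (missing completely at random — the
real missingness mechanism is unknown). Cleaning a defected dataset must
recover the undefected record set exactly (same record ids, same outcomes),
and the audit counters must equal the ledger counts exactly; both are
asserted end to end.

What the generator does **not** emulate: real covariate-dependent service
timing, heat-detection that depends on the animal, abortions, carryover of
genetics across years, or any real herd's management quirks. Passing tests
demonstrate internal consistency of the pipeline and estimators under the
stated generative model, not fidelity to any real herd.

## Estimation

* **LR** — IRLS with step-halving; converged when the maximum absolute
  score is < 1e-8 or the relative log-likelihood change is < 1e-10;
  covariance is the inverse Fisher information; rank deficiency is detected
  by pivoted QR and reported with the offending columns. Separation raises
  once any coefficient exceeds ±15 on the logit scale: under separation the
  score vanishes along the divergent path, so the bound itself is the
  detection rule. The bound is disabled inside the linearity diagnostic,
  whose x·ln x column is legitimately near-collinear with x.
* **MLR** — the marginal likelihood integrates one Gaussian intercept per
  herd-year by adaptive Gauss–Hermite quadrature (default 9 nodes; 1 node =
  Laplace), centred and scaled at the per-group posterior mode found by
  Newton iteration, vectorized over groups. (β, log σ) are optimized by
  L-BFGS-B from an LR warm start; the covariance comes from a central
  finite-difference Hessian at the optimum. σ̂ below 1e-4 is reported as a
  boundary fit, not an error. The implementation reproduces lme4's
  `glmer(nAGQ=25)` on a generated fixture to ~1e-4 in coefficients and SD
  (asserted by a test that shells out to Rscript).
* **GAM** — parametric factors plus one penalized smooth per continuous
  term: a 10-function cubic B-spline basis on quantile knots, an exact
  second-derivative penalty (two-point Gauss–Legendre per knot span),
  sum-to-zero constraints, and per-term smoothing weights by GCV
  (n·deviance/(n − edf)²) over a log-spaced grid (product grid across
  terms). The penalty null space is the centred linear function, so λ → ∞
  collapses a smooth to the linear fit; λ around 1e9 reproduces linear LR
  predictions to ~1e-8 (beyond ~1e12 the normal equations lose precision,
  so the "infinite" limit is exercised at 1e9). Prediction clamps inputs to
  the training range (constant extrapolation).
* **Stepwise selection** follows the published protocol: univariate screen
  at P ≤ 0.2 (likelihood-ratio tests, factors as blocks), backward drops at
  P > 0.2, forward adds at P ≤ 0.05 with two-way interactions of included
  terms in the pool, alternating to a fixed point; scan order alphabetical;
  hierarchy respected. Note the P ≤ 0.2 retention rule *by design* keeps
  each pure-noise candidate with probability ≈ 0.2 — the protocol is
  faithful, not conservative.
* **Variable importance** ranks coefficients by |z| (LR/GAM; one entry per
  factor level, one per smooth scored by its largest basis-coefficient |z|)
  and by P-value for MLR. Odds-ratio tables are exp(coef) with Wald
  intervals; reference levels print OR 1 with no interval; main effects
  involved in an interaction carry no P-value.

## Evaluation

Classification is positive iff probability ≥ threshold (the ≥ convention
reproduces the degenerate all-positive column when every prediction ties
the threshold). All 0/0 ratios and a zero-denominator MCC return 0, matching
the printed convention for the all-positive classifier. AUC is trapezoidal
over the tie-grouped ROC sweep and equals P(score⁺ > score⁻) + ½P(=). The
optimal threshold maximizes Youden's J over observed probabilities, ties to
the smallest (no criterion is named in the source; this one is documented).
Hosmer–Lemeshow uses ten near-equal groups by stable sort on predicted
probability, both outcome cells, df = groups − 2; groups with an empty
expected cell are merged with a warning. Note the χ²(g−2) reference applies
to probabilities fitted on the evaluated data; externally supplied true
probabilities are over-dispersed relative to it. Calibration bins are 15
equal-width intervals with exact (Clopper–Pearson / F-form) intervals; bins
under 10 records are flagged unplotted. The unreliability test is a
2-df likelihood-ratio test of logistic recalibration on logit(p) against
intercept 0 / slope 1. Binned residuals use ⌊√n⌋ equal-sized groups by
sorted probability; MACE is the mean absolute group deviation, in percent.

### Why held-out MACE sits near 6–7%, not below 4%

At n ≈ 600 and prevalence 0.78, ⌊√n⌋ ≈ 24 groups hold ~25 records each, so
even a *perfectly* calibrated predictor has per-group deviations of SD
√(p(1−p)/25) ≈ 0.083 and E[MACE] ≈ 6.5%. Zeroing the random intercepts adds
a systematic Jensen-type overprediction (E_u[expit(η+u)] < expit(η) for
η > 0), worth roughly another 3 points of local bias. Any MACE below 4% at
this sample size would require coarser grouping (≲ 7 groups). The package
reports the honest value under its stated defaults; the grouping is
configurable (`n_groups`).

## Pipeline and reproducibility

One master seed spawns per-stage seeds through `numpy.random.SeedSequence`
(kept below 2³¹); identical configuration and seed reproduce every number
in the report bundle bit for bit (asserted). Fits themselves are
deterministic; only simulation consumes randomness. The 70/30 split uses
per-class ceiling rounding, which reproduces the 1,396/597 partition from
1,549 positive / 444 negative records; bootstrap resampling (default 2,000
iterations) is provided for training-variability summaries, while reported
coefficients are always the single fit on the full training set (how the
original bootstrap-wrapped coefficients were aggregated is unstated; a
single refit is the defensible default).

Problem sizes in the shipped experiments — study-sized herds of ~2,000–2,300
services, 20,000-service odds-ratio recovery, 60 herd-years × 40 services
for variance recovery, 500-replicate null-rate checks at n = 600 — were
chosen so each estimate's Monte-Carlo error is small against its acceptance
tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

* The three problem-season parameters and the rebreeding probability are
  explicit guesses; no claim of fidelity to the source data's unstated
  rules.
* The GAM's basis size, knot placement and GCV grid are this package's
  choices; the original smoother is unspecified.
* MLR prediction ignores the random effects by design (new herds have no
  estimated intercept); conditional prediction for known herd-years is not
  implemented.
* Natural (bull) services, body weight/condition covariates and economic
  indices are out of scope.
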