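# Methods

This note documents the statistical model, the selection procedures, the
synthetic-data generator, and the numerical and design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Outcome model

Five-year all-cause death is modelled by sex-stratified logistic regression

    logit π_i = β₀ + β₁ g₁(x̄_i) + β₂ g₂(x̄_i) + β₃ h(ā_i) + β₄ s_i (+ interactions)

with x̄ = BMI/10, ā = age/10, s the ever-smoker flag. g₁, g₂ are a degree-2
fractional polynomial (FP2) of x̄ with powers from
S = {−2, −1, −0.5, 0, 0.5, 1, 2, 3}; power 0 denotes ln, and a repeated pair
(p, p) denotes {x̄^p, x̄^p ln x̄} (for (0,0): {ln x̄, (ln x̄)²}). Age enters
as a degree-1 FP (a deliberate cap against collinearity with its own
transforms). A logistic model on a fixed horizon is used rather than a
proportional-hazards model; the cost is that exact death timing is ignored,
which is why the generator carries `time_to_death` only for the horizon
recode and the early-death sensitivity analysis.

**Scaling and centering.** Each covariate is pre-divided by a scale (10 for
both BMI and age) and each transformed column is centered by subtracting the
transform evaluated at the covariate's unweighted sample mean,
center_j = g_j(mean(x)/scale). Centering affects only the intercept (a
tested invariant); this particular convention makes the intercept the linear
predictor of a mean-covariate never-smoker and reproduces published
age-specific optima exactly when combined with interaction folding (below).
Centering at the mean of the *transformed* column is the other defensible
convention; it was rejected because it does not reproduce those worked
examples.

## Weighted fitting

`weighted_glm.fit_logistic` maximises the weighted Bernoulli log-likelihood
by Newton/IRLS with step-halving: probabilities clipped to
[1e−12, 1−1e−12], convergence when the relative deviance change falls below
1e−10, cap 100 iterations (hitting the cap flags `converged=False` instead
of raising; a deviance that collapses to ~0 flags suspected perfect
separation). The covariance is the inverse weighted Fisher information
(model-based), matching the deviance-difference testing framework; a
design-based sandwich covariance is available via `compute_sandwich=True`.

**Weight scale.** Survey weights are treated as pseudo-likelihood frequency
weights and are normalised to mean 1 (sum = n) before fitting, because
χ² deviance tests and Wald covariances are calibrated only on the
sample-size scale — raw pooled-year weights carry an arbitrary population
scale and a 1/n_years factor that would shrink every test statistic and
inflate every variance by the same factor. Coefficients are invariant to
this rescaling; `normalize_weights=False` restores the raw-scale
likelihood. This testing procedure is exact only for mildly dispersed,
non-informative weights; with strongly dispersed real survey weights the
naive χ² reference over-rejects by roughly the design effect 1 + CV², and a
design-effect correction (not applied here, to match the published
procedure) would be needed.

## Function selection

The closed test (`fsp_decide`) for one covariate, at a single α (default
0.05, no multiplicity correction):

1. best FP2 vs null, df 4 — not significant ⇒ omit the covariate;
2. best FP2 vs linear, df 3 — not significant ⇒ keep linear;
3. best FP2 vs best FP1, df 2 — significant ⇒ FP2, else FP1.

"Best" means minimum deviance over the 36 FP2 (8 FP1) candidates, ties
broken by ascending lexicographic power order (within 1e−8). Forced-in
covariates skip step 1. `mfp_cycle` applies this per covariate, visiting
covariates in descending Wald significance from a preliminary all-linear
fit (the standard MFP convention; with two continuous covariates the result
is insensitive to order), re-selecting each given the others' current
forms, until a full cycle changes nothing (cap 5 cycles, then flagged
non-converged). Non-forced binary covariates get a df-1 inclusion test.

**Size of the procedure.** Step 1 charges 4 df for a 2-column model plus
the discrete power search. Over BMI's narrow effective range the 36
candidate bases are highly collinear, so the best-candidate deviance gain
under the null behaves closer to χ²₂ than χ²₄ and the covariate-level
type-I error is well below the nominal α (measured ≈1% at α = 5% in the
suite's null simulation). This is the procedure's documented family-wise
conservatism, inherited by design; users wanting covariate-level size closer
to α should raise α for the inclusion test.

## Interactions (MFPI) and graphical check

With main-effect forms frozen, each candidate interaction adds the products
of the continuous variable's FP columns with the partner's column(s)
(age × BMI: 2 columns, df 2; age × smoking: 1 column, df 1) and is tested by
deviance difference; forward selection adds the most significant candidate
below α and re-tests the rest. The age × smoking interaction is reported
both as a product coefficient and as stratum-specific age slopes with
delta-combined standard errors. Detected interactions can be corroborated
with `lowess_logit_check`: within-stratum death rates in equal-count bins,
continuity-corrected as (d + 0.5)/(n + 1), logit-transformed and
lowess-smoothed (span 0.6, one robustness iteration — unstated in standard
practice, fixed here for reproducibility and configurable).

## Nadir estimation

Setting the derivative of the BMI block to zero gives closed forms
(centering constants drop out):

* repeated (p, p), p ≠ 0: ln x̄* = −(p b₁ + b₂)/(p b₂)
  (for (−2,−2): x̄* = exp((b₂ − 2b₁)/(2b₂)));
* repeated (0, 0): ln x̄* = −b₁/(2b₂);
* distinct nonzero p₁ ≠ p₂: x̄* = (−b₁p₁ / (b₂p₂))^(1/(p₂−p₁))
  (linear-quadratic (1,2): x̄* = −b₁/(2b₂));
* one zero power (0, p): x̄* = (−b₁/(b₂ p))^(1/p).

The second derivative at x̄* is checked numerically; a maximum or a
monotone curve raises, and `nadir_delta_ci` then falls back to a bounded
numeric search whose result is flagged `boundary` with no interval (the
delta method is invalid there). With an age × BMI interaction the age
contribution is folded into effective coefficients b₁' = b₁ + c₁·g(age),
b₂' = b₂ + c₂·g(age) at the requested profile before solving, which is what
makes the female optimum age-dependent. Delta-method standard errors use
the analytic gradient of each closed form (chain-ruled through the folding),
cross-checked at run time against central differences (relative step 1e−6;
disagreement beyond 1e−4 raises). Closed forms are verified in the suite
against an independent grid + golden-section minimiser (polished by a
Richardson-extrapolated derivative root-find, since pure function-value
minimisation cannot certify 1e−6 BMI units near the top of the range in
double precision).

Coverage note: in the suite's simulation at the study's stratum size the
95% delta interval for the male optimum covers the generating truth
slightly above nominal (≈97%). The delta se itself matches the empirical
sd of the estimates; the overcoverage arises because replicates with larger
estimation errors also produce larger estimated se (small-|b₂| draws widen
both), a characteristic finite-sample property of delta intervals for
ratio-type quantities.

## Comparator models and sensitivity refits

The FP fit is compared with: untransformed-linear BMI (nested, df 1),
linear-quadratic BMI (equal parameter count — the signed deviance
difference is reported and, because the LQ model is the (1,2) candidate,
can never favour LQ), and categorical BMI (WHO classes
[18.5,25)/[25,30)/[30,35)/[35,40)/40+, reference Normal; non-nested).
For non-nested comparisons no χ² p-value is emitted unless the
`chi2_for_nonnested` compatibility switch is set, mimicking reporting
conventions that apply the χ² reference regardless. A 30-bin narrow scheme
(1-unit bins to 40, 2-unit bins to 54, one open bin; reference = the bin
containing BMI 22, which shifts only the displayed intercept) supports the
bin-wise validation of the curve. Sensitivity refits re-run the full MFP
selection after dropping deaths within one year of baseline or BMI > 50 and
return curves on a common grid; overlay comparisons should anchor the BMI
logit block at a common reference BMI since refits re-center on their own
sample.

## Synthetic cohort generator

The generator emulates the pooled 1997–2000 adult cohort structure per sex:

* **age**: truncated normal on [18, 99], sd 17.5 (a realistic adult-US
  spread; only the means are published), location solved so the truncated
  mean equals the published 45.49 (M) / 47.13 (F);
* **smoking**: Bernoulli at the published 54.93% / 40.47%;
* **BMI**: shifted lognormal, parameters fitted once (least squares, at
  package build time, frozen in `fpmort.reference`) so the WHO-category
  prevalences conditional on BMI ≥ 18.5 match the published ones to within
  0.25 percentage points;
* **weights**: gamma with mean 1 and CV 0.2, divided by the 4 pooled years.
  The mild dispersion keeps the naive weighted-likelihood tests calibrated
  (design effect ≈1.04); real survey weights are more dispersed and
  cluster-structured, which the generator deliberately does not emulate;
* **outcome**: Bernoulli from the published FP coefficient truth with the
  same scaling/centering conventions as the analysis; the generator
  intercepts are recalibrated (−3.993 M, −4.300 F) so overall
  simulated death rates match the published 6.37% / 5.55%, because the
  published intercepts refer to unpublished centering constants;
* **death timing**: uniform on (0, horizon] (the logistic model ignores
  timing); a `reverse_causation` hook injects excess first-year deaths
  below a BMI threshold for the early-death sensitivity analysis.

Covariates are drawn independently within sex. Consequences: the generator
reproduces marginals and the BMI–mortality curve, but it cannot carry the
full joint covariate–outcome information of the real linkage data — its
deviance signals for the BMI effect and the interactions are smaller than
the published ones (a few tens rather than a few hundreds per stratum), and
passing tests demonstrate correctness of the machinery under these
conditions, not the published test statistics. Records with BMI below 18.5
or above the 99.99 recording ceiling are generated and then removed by
`apply_inclusion`, mirroring the study's exclusion flow (age < 18, BMI
< 18.5, BMI missing/> 99.99, unknown smoking; tallied by reason;
idempotent).

## Problem sizes used in the suite

Unit and property tests run on cohorts of 8k–65k subjects; the simulation
checks use 200 null cohorts of 20k (closed-test size), 5 cohorts of 50k
(power/recovery), and 500 cohorts of 50k (delta-CI coverage) — sizes chosen
to keep Monte-Carlo error near or below the tolerances being asserted.

## Known limitations

* Naive weighted-likelihood inference: no design-effect or clustering
  corrections (sandwich covariance available but not default).
* The closed test's covariate-level size is conservative (see above).
* FP2 families adjacent in S are nearly aliased at realistic sample sizes;
  selection among them (e.g. (−2,−1) vs (−2,−0.5)) is unstable even when
  the fitted curves are indistinguishable — curve-level conclusions are
  robust, power-label conclusions are not.
* Absolute predicted probabilities from the published coefficient tables
  are not recoverable (centering constants unpublished); the package only
  reports predicted mortality for models it fits itself.
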