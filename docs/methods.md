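# Methods

This note documents the statistical machinery, the conventions chosen where
census data leave them open, and what the synthetic-forest generator does
and does not emulate.

## 1. Demographic rates

The per-interval annualised mortality rate is
m = (1 − (N_t1/N_t0)^(1/T)) × 100 (% yr⁻¹). Counting conventions:

- a tree enters N_t0 only from its first census with a live record
  (recruits contribute nothing before recruitment);
- a tree must be observed at the interval's end — alive or dead — to be
  counted; stems that vanish without a death record (`lost`) are censored
  out of both N_t0 and N_t1 for all later intervals;
- mode-specific rates apply the same formula with N_t1 = N_t0 − deaths of
  the target recorded mode, so deaths by the other mode (or unassessed)
  count as survivors of that mode. Standing and broken/uprooted death
  counts therefore partition the total exactly.

Plot-level rates are census-interval-length-weighted means of interval
rates. Basin/region summaries resample plots uniformly with replacement
(B = 10,000 by default); the plot-area weights enter each replicate's
weighted mean, not the sampling probabilities; the CI is the percentile
2.5/97.5 interval (not BCa). Regional comparisons use Tukey's HSD on
plot-level rates (pooled-variance studentized range, Tukey–Kramer for
unequal group sizes), with a hand-rolled insert/absorb compact letter
display. Regional bootstrap means weight by area within the region;
basin-wide weighting is obtained by summarising the pooled table.

## 2. Mode-of-death proportions and the interval-length correction

Plot proportions use assessed deaths only (unassessed stems leave both
numerator and denominator) and require the eligibility rule: at least 50 %
of dead stems assessed and at least 5 assessed. The correction fits
ordinary least squares of the plot proportion on the plot's mean
census-interval length, centred to mean zero **over the plots entering the
specific fit**, so the intercept is the corrected proportion at the
network's mean interval. Proportions are modelled on the identity scale
(not logit); fitted values outside [0, 1] are reported as-is with a
warning, never clipped — by OLS linearity the corrected standing and
broken proportions still sum to one exactly. The regional model uses
cell-means coding (one mean per region plus the shared centred-CIL slope);
per-region CIs are t-based on the adjusted mean (the headline quantity),
and pairwise contrasts carry studentized-range-adjusted p-values.
statsmodels performs the OLS fits.

## 3. Survival records

One record per tree (default): the clock starts at the tree's first
observed census and ends at the census where it was found dead (event) or
its last census (censored). Covariates follow the census convention —
diameter D from the penultimate recorded census, relative growth over the
antepenultimate→penultimate interval. Exclusions, applied in this order
and all counted in the report: plots with fewer than 3 censuses; palms;
trees recorded fewer than 3 times; missing diameters at the measurement
pair; relative growth below −5 % yr⁻¹ (impossible shrinkage = measurement
error). Death time is the discovery census by default; an interval
midpoint option exists. An `entry="penultimate"` option restricts risk
time to the growth-measurement interval onward, for sensitivity analysis.

`counting_process=True` instead emits one row per census interval from the
second observed interval onward, on the **plot-calendar clock** with
delayed entry, covariates updated each interval (D from the interval's
first census, growth over the preceding interval). This representation
matches a piecewise-constant time-varying hazard exactly and is the one
used for parameter-recovery validation: the single-record convention
measures growth just before exit, which for survivors means at the end of
monitoring — with a covariate that declines mechanically over each tree's
life this induces a survivor-measurement artifact that can even flip the
sign of the growth coefficient. During development the per-tree clock was
also found to be poorly calibrated for trending covariates at realistic
scales, which is why the counting-process rows use calendar time.

Units on the model scale: D in metres (size coefficients are then O(1–10)),
relative growth in % yr⁻¹, max D in mm, species mean growth in mm yr⁻¹,
wood density in g cm⁻³, WDA in mm. Diameters are mm at I/O.

Trait attachment cascades species value → genus mean (across species in
the genus) → family mean → plot mean over individual stems (so abundant
species weigh more); the level used is recorded per trait per record. The
cascade is deterministic and order-invariant.

## 4. The hazard engine

From-scratch Cox partial likelihood with:

- **Ties**: Efron by default (census data put many deaths at the same
  time); Breslow behind a flag. Risk sums are computed by a descending-time
  sweep with segment Gram matrices, O(n·p²) per evaluation.
- **Delayed entry**: records may carry `start`; the risk set at event time
  t is {start < t ≤ stop}, implemented as a difference of two cumulative
  sums.
- **Optimisation**: damped Newton–Raphson (step halving on overshoot),
  convergence at relative log-likelihood change < 1e-9 or 50 iterations.
  Coefficients with per-SD effects above 15 raise a monotone-likelihood
  (separation) warning.
- **Frailty**: a shared per-plot log-normal random effect estimated by
  penalized partial likelihood — the design is augmented with plot
  indicators penalised by 1/θ — with θ chosen by maximising the Laplace
  approximation to the marginal likelihood,
  lm(θ) = PPL(β̂, b̂) − ½ log det(θ·H_bb + I). θ → 0 recovers the plain
  partial likelihood, so homogeneous data land on the boundary θ = 0
  rather than failing. Fixed-effect SEs come from the β block of the
  inverse penalized information. Simulation checks: θ ∈ {0, 0.25, 1}
  recovered as ≈ {0.00, 0.29, 1.11} at 60 plots × 120 trees (slight
  upward finite-sample bias at large θ); a gamma-frailty EM backend was
  considered and not implemented — the log-normal penalized form is the
  single backend, cross-validated by simulation instead.
- **Wald χ²** per term is (β/SE)²; likelihood-ratio χ² by drop-one refits
  is available alongside (`lr_tests`), with D/D² dropped jointly.
- **AIC** = −2·loglik + 2·k with k the number of fixed-effect terms, plus
  1 when θ is estimated; for frailty fits the Laplace marginal
  log-likelihood replaces the partial log-likelihood so that ladders mix
  frailty and non-frailty rows coherently. ΔAIC > 2 is read as a
  meaningful difference.
- **Model ladder and stepwise**: the standard ladder fits the full model,
  every drop-one reduction, the two single-group models and the null on
  the same record set. Bidirectional stepwise AIC respects the D/D²
  hierarchy (D² only with D; D not removable while D² present) and
  re-estimates θ at each candidate by default (`refit_frailty=False`
  freezes the full-model θ as a fast approximation).
- **VIF** screening via statsmodels (auxiliary R²; values > 10 flagged,
  exact collinearity reported as ∞).
- **Mode-specific fits** treat deaths of the other (or unassessed) mode as
  censored at their death time.

Covariates enter unstandardised, so coefficients are on the natural scales
above.

## 5. The synthetic forest

The generator emulates a four-region network of 0.5–2 ha plots (~550
stems ha⁻¹ ≥ 10 cm, plus a sub-threshold recruit pool), censused at
2.8 ± 0.7 yr intervals over 25 yr. Species (default 200) carry wood
density ~ N(0.65, 0.15²) g cm⁻³ clipped to (0.2, 1.1), maximum diameter
~ logN(log 420, 0.35²) mm, mean growth ~ logN(log 1.2, 0.55²) mm yr⁻¹ and
WDA ~ N(−150, 100²) mm, with a log-normal rank-abundance distribution.
Individual growth is the species mean times a mean-one log-normal
multiplier (σ = 0.5); diameters grow linearly and are measured with
1.5 mm Gaussian tape error (recruitment at measured ≥ 100 mm is
permanent).

Death times are drawn **exactly** by inversion: covariates are held
piecewise-constant between censuses, so each interval has a flat hazard
h₀·exp((x − x_ref)′β + b_plot) and the cumulative hazard inverts in closed
form. The growth covariate in the hazard is the *observable* one — growth
over the preceding interval relative to its starting diameter — so the
generating model coincides with what a census can measure. Covariates are
centred at a reference tree purely so that h₀ (default 0.02 yr⁻¹) is the
hazard of an average stem; centring is absorbed by the baseline and never
touches β. Default β magnitudes mirror a fitted pan-scale risk model
(e.g. mean growth +0.2, wood density −0.7); default frailty variance is
0.25 (a moderate plot effect, chosen once — the source analyses do not
report θ).

Mode of death: a dying tree is standing with probability
logistic(0.5 − 0.6 · relgrowth), making slow growers die standing more
often (intercept/slope chosen to give a ≈50/50 standing–broken mixture at
typical growth). Discovered-dead stems are assessed with probability 0.85.
Post-mortem breakage then flips recorded standing deaths to
broken/uprooted with probability 1 − exp(−r·τ), τ the time from true death
to discovery, r = 0.04 yr⁻¹ by default — the bias the CIL correction is
built to remove. Trait missingness defaults to the 14 %/6 %/3 %
species/genus/family regime, applied so that every imputation branch is
exercised (species-level masking falls to the genus mean; whole-genus
masking to the family mean; whole-family masking to the plot mean).

What the generator does **not** emulate: spatially explicit treefall gaps
or spatial correlation within plots, climate anomalies and temporal trends
in rates, point-of-measurement changes and buttress growth, taxonomic
misidentification, and species interactions. A green simulation test
therefore establishes estimator correctness under the stated model, not
robustness to these real-data features. A crude burn-in knob
(`burnin_yr`) ages the initial cohort toward a quasi-equilibrium size
structure by replacing baseline-hazard casualties with fresh recruits; it
defaults to off.

## 6. Numerical and design choices

- Dates are decimal years; census interval lengths are date differences.
- Plot merging (< 1 km great-circle distance, summed areas, transitive
  within a connected component) requires census schedules to align within
  0.5 yr per census; incompatible plots stay unmerged and are reported.
  Merged plots must agree on region — a conflict raises rather than
  guessing.
- The bootstrap resamples plots uniformly and weights inside the
  replicate mean; it is deterministic given (values, weights, B, seed).
- The regional mode model drops regions contributing a single plot, with
  a warning.
- Exclusion reports are exhaustive: every dropped plot, tree and record
  carries a named rule, and the pipeline manifest records seeds,
  thresholds, stage status and exclusion counts, sufficient to reproduce a
  run bit-for-bit at a fixed package version.

## 7. Known limitations

- The Laplace-profile frailty variance has finite-sample bias (upward at
  large θ, toward zero for very small clusters) and no standard error is
  reported for θ.
- Wald CIs on heavily tied census data are slightly anti-conservative
  (observed ~92–94 % coverage at nominal 95 % in the acceptance
  experiments).
- The single-record covariate convention is faithful to census practice
  but subject to the survivor-measurement artifact described in §3; use
  the counting-process representation when the growth coefficient itself
  is of interest.
- Proportional-hazards diagnostics (Schoenfeld residuals), survival-curve
  prediction and time-varying baseline estimation are out of scope.
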