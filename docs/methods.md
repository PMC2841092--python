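# Methods

This note records the model, its assumptions, the numerical choices, and
what the synthetic-data validation does and does not demonstrate.

## Exposure model

Daily ethanol intake among current drinkers is modeled on (0, ∞) g/day by
one of three two-parameter families: log-normal (location μ, log-scale σ),
gamma (shape k, scale θ g/day), Weibull (shape γ, scale θ g/day). All three
are unimodal and right-skewed and differ mainly in the tail. Fitting is by
maximum likelihood: the log-normal MLE is closed form (moments of log x);
for gamma and Weibull the two-parameter problem profiles down to one scalar
shape equation solved by Newton–Raphson (method-of-moments start, relative
tolerance 1e-8, 200-iteration cap, halving/doubling fallback when a step
leaves the domain). The gamma profile uses log k − ψ(k) = log x̄ − mean(log x),
so the fitted mean k̂θ̂ equals the sample mean *exactly* — the property the
shifting step depends on. Optional survey weights enter as frequency-style
log-likelihood weights; a weighted fit equals the fit to the corresponding
replicated sample.

Zero or negative volumes are outside every family's support: the survey
reader reclassifies exact zeros among "current" drinkers as abstainers and
drops missing volumes, logging counts by sex. Zero-variance drinker data
raise a convergence error — no two-parameter family is identified there.

## Fit comparison

Observed drinker volumes are binned at 10 g/day bandwidth into half-open
bins [0,10), …, [90,100), [100,∞); expected masses are CDF differences of
each fitted family; cells are (O − nπ)²/(nπ), reported per bin plus a total
and a below-100 subtotal. These are descriptive indices for ranking
families (ties broken alphabetically), not tests: no pooling of sparse
bins (a warning fires below expected count 5) and no p-values.

## Triangulation (upshifting)

Two assumptions carry the method: (1) survey abstention proportions are
taken as true; (2) one coverage rate applies to all strata. Coverage is the
weighted mean g/day over **all** adults (abstainers as zeros) divided by
the per-capita value, converted from liters/adult/year with ethanol density
789.24 g/L and 365 days/year (both configurable; the conversion constants
are this package's choice). Every stratum's drinker mean is multiplied by
target_fraction/coverage; target_fraction is 1.0 by default with 0.9/0.8
recommended as sensitivity levels.

The shifted SD is predicted by SD* = a·mean* + b·sex (men 0, women 1). The
original calibration of (a, b) on a large multi-country collection of
fitted gamma distributions is not redistributable, so the shipped defaults
(a = 1.17400046, b = 1.00320643 g/day) are recovered by least squares
through the origin from the published US NESARC 2001–2002 stratum table
bundled in `alcofit.reference` (R² ≈ 1.0; every published SD reproduced
within 0.005%). The male rows imply a zero intercept — SD*/mean* is one
constant for men — which forces a single male shifted shape
k = (1/a)² ≈ 0.7255 (printed as 0.726 in the source table). Fitting with a
free intercept returns ≈ −3e-4, confirming the origin constraint
empirically. The published per-stratum shifted means imply a slightly
different constant (≈1/0.521) than the rounded headline coverage 0.529;
the package therefore treats coverage as a full-precision input computed
from the data rather than a quoted constant. Only the gamma family is
shifted: its moment relations k = (mean/SD)², θ = SD²/mean map the
(mean*, SD*) pair straight back to parameters; there is no comparable
closed-form shift for the Weibull or log-normal.

## Attributable fractions

The component-cause form AAF = E/(1+E) with
E = P_form(RR_form − 1) + P_cur ∫P(x)(RR(x) − 1)dx is used throughout; the
categorical form replaces the integral by Σ P_i(RR_i − 1) with
P_i = P_cur(F(u_i) − F(l_i)). The formula is validated against the Levin
closed form (single exposed category) and against exact
continuous/categorical agreement for piecewise-constant RR. Default
category bounds follow the conventional volume classes (men 0–40/40–60/60+,
women 0–20/20–40/40+ g/day); category RRs and the RR(x) curve are external
configuration — the package ships one *illustrative* log-linear curve
(β = 0.008 per g/day, RR_form = 1.4, i.e. RR doubling about every 87 g/day)
and no curated disease-specific risk function, so published disease AAF
tables are not reproduction targets.

Numerics: the exposure integral is a mass-weighted midpoint rule — cell
edges every 0.01 g/day (configurable) from 0 to the cap or to a 300 g/day
default upper limit, split additionally at RR discontinuities; each cell
contributes [F(upper) − F(lower)] · (RR(midpoint) − 1). A plain trapezoid
on the density is inadequate here: fitted shapes are typically k < 1, whose
density diverges at 0, while the CDF-difference rule is exact for constant
RR (machine-precision Levin agreement), exact for step RRs, and O(h²) for
smooth RRs. A generic composite trapezoid is still provided (and used, e.g.
for density-normalization checks away from the origin). Probability mass
above the integration limit is assigned RR(limit): with a cap this is the
"retain at RR(cap)" convention (a truncation flag discards the excess risk
instead); without a cap it makes the 300 g/day default an effective
numerical cap — negligible for gamma tails at these scales, and raised
explicitly in tests that compare against closed forms with slowly decaying
integrands.

## Bootstrap

Respondent-level nonparametric bootstrap within a stratum (default 10,000
replicates): resample with replacement, recompute status prevalences, refit
the drinker gamma, reapply the shift, recompute the AAF; report the SE of
the replicate AAFs and the 2.5/97.5 percentile interval. The coverage
constant and SD-regression coefficients are held fixed across replicates —
they derive from external totals and an external calibration, not from the
stratum. Replicate r draws from spawned substream r of the mandatory seed,
so results are bitwise reproducible. All-abstainer (or otherwise
unfittable) resamples are dropped and counted; more than 1% dropped aborts.
For the shifted-AAF target the replicate AAF depends on the resample only
through the prevalences and the drinker mean (the gamma MLE preserves the
mean and the shifted SD is a function of the shifted mean), so the refit is
skipped there as an exact algebraic shortcut; a stratum of identical
respondents consequently returns SE 0 with a zero-width interval.

## Synthetic data and what validation shows

The generator draws, per stratum, a multinomial status split and gamma
"true" volumes for current drinkers, reported as true × one shared
multiplicative underreporting factor (default 0.529). The default 30 strata
(2 sexes × 3 age groups × 5 ethnicities, ≈1,436 respondents each, total
≈43,100) take their true drinker gammas from the published upshifted
stratum table, so the truth satisfies the SD regression by construction;
abstention proportions are plausible round values by sex and age with no
claim of demographic fidelity.

Validation results on this truth: with factor 0.53 and 50,000 respondents
per stratum the pipeline recovers every stratum's true drinker mean within
3% (observed ≈1.9% worst-case) and the illustrative-RR AAF within 2
percentage points (observed ≈0.25); the generating family wins the
chi-square comparison in ≥80% of replicates at n = 5,000 (observed 100%);
bootstrap 95% intervals cover the true-parameter AAF for ≈95% of synthetic
strata (observed 93.5% over 200 replications of n = 2,000 with 1,000
replicates each — replicate counts and grid steps scaled for a simulation
study, as recorded in each test).

What this does **not** show: the generator's multiplicative-undercoverage
mechanism is the method's own Assumption 2, so recovery on synthetic data
cannot detect differential underreporting (e.g. selective nonresponse of
heavy drinkers), survey design effects (clustering, weighting,
oversampling), reporting heaping at round numbers, or misclassification of
drinking status — all of which real surveys exhibit. Passing tests certify
internal consistency of the triangulation machinery, not the truth of its
assumptions in any real population.

## Known limitations

- One coverage constant for all strata; differential undercoverage is an
  extension hook, not implemented.
- Uncertainty in the per-capita total and in the SD-regression
  coefficients is not propagated (bootstrap conditions on both).
- Only the gamma family can be shifted; Weibull, though usually the best
  descriptive fit, is descriptive-only here.
- The default SD coefficients are calibrated to one country-year's
  published table; for other populations, recalibrate with
  `fit_sd_regression` or override `ShiftConfig`.
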