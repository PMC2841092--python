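# alcofit

Triangulation of survey and per-capita data on alcohol exposure, for
epidemiologists who need population distributions of drinking volume that
are consistent with national consumption totals.

## The problem

Alcohol volume is causally related to a large share of the global burden of
disease, and the attributable fraction of a disease depends on the whole
distribution of grams-of-ethanol-per-day in the population, by sex and age.
Two data sources exist and disagree: surveys give the *shape* of the
distribution (and abstention rates) but typically cover only 30–60% of the
total volume implied by adult per-capita consumption (APC) statistics from
sales and taxation, which in turn carry no demographic detail.
Triangulation reconciles them: take abstention and relative stratum means
from the survey, take the total from APC, and upshift.

## The method

1. **Fit.** Among current drinkers in each sex × age × ethnicity stratum,
   fit right-skewed two-parameter families — log-normal(μ, σ), gamma(k, θ),
   Weibull(γ, θ) — by maximum likelihood (Newton–Raphson on the profile
   score; the log-normal MLE is closed-form). Fit quality is compared by a
   binned chi-square with 10 g/day bandwidth up to 100 g/day plus an open
   top bin.
2. **Shift.** The gamma family is used for shifting because its MLE mean
   equals the sample mean and its parameters invert from moments:
   k = (mean/SD)², θ = SD²/mean. With coverage
   c = (survey volume)/(APC volume), every stratum's drinker mean is
   rescaled by the same constant, mean* = mean · t/c (t = 1.0, with 0.9 and
   0.8 as sensitivity levels), and the unobservable shifted SD is predicted
   by a calibrated regression SD* = 1.1740 · mean* + 1.0032 · sex
   (sex: men 0, women 1), whose coefficients the package recovers by least
   squares from the published US NESARC 2001–2002 stratum table.
3. **AAF.** With prevalences P_abs (lifetime abstainers, the RR reference),
   P_form (former drinkers, scalar RR_form) and P_cur (current drinkers
   with density P(x)) the alcohol-attributable fraction is

       AAF = E / (1 + E),   E = P_form(RR_form − 1) + P_cur ∫ P(x)(RR(x) − 1) dx

   in continuous form, or with category prevalences replacing the integral
   in categorical form (single category ⇒ the Levin formula). RR inputs are
   configuration: log-linear, linear, an interpolated table, or a category
   scheme; an optional 150 g/day cap bounds tail influence.
4. **Uncertainty.** Nonparametric bootstrap over respondents within the
   stratum: resample, recompute prevalences, refit, reshift, recompute the
   AAF; percentile 95% intervals with the SE alongside.

Because the restricted survey microdata cannot be redistributed, the
package includes a synthetic-data generator with the same structure
(30 strata, multinomial drinking status, gamma drinker volumes, one
multiplicative underreporting factor, default 0.529) whose known truth
validates every stage end to end.

## Worked example

```python
import alcofit as af

specs = af.default_specs(n_per_stratum=2000)          # 30 strata, known truth
survey = af.generate_survey(specs, seed=7)

percapita = af.percapita_to_grams_per_day(8.75)       # liters/adult/year -> g/day
coverage = af.coverage_rate(survey["grams_per_day"], percapita)
print(f"per-capita: {percapita:.2f} g/day, coverage rate: {coverage:.3f}")

stratum = survey[(survey.sex == "men") & (survey.ethnicity == "White")
                 & (survey.age_group == "35 - 54")]
drinkers = stratum.loc[stratum.status == "current", "grams_per_day"].to_numpy()
fitted = af.fit_mle(drinkers, "gamma")

config = af.ShiftConfig(coverage=coverage)
shift = af.shift_distribution(fitted, "men", config)
print(f"shifted mean: {shift.original.mean:.2f} -> {shift.shifted_mean:.2f} g/day, "
      f"k={shift.shifted.k:.3f}, theta={shift.shifted.theta:.2f}")

pop = af.PopulationStructure(
    p_abs=float((stratum.status == "lifetime_abstainer").mean()),
    p_form=float((stratum.status == "former").mean()),
    p_cur=float((stratum.status == "current").mean()),
)
risk = af.RiskFunction.loglinear(beta=0.008, rr_former=1.4)
before = af.aaf_continuous(pop, risk, fitted.params)
after = af.aaf_continuous(pop, risk, shift.shifted)
print(f"continuous AAF: {100*before.aaf:.1f}% (survey) -> {100*after.aaf:.1f}% (shifted)")

boot = af.bootstrap_aaf(stratum, risk, config, n_reps=1000, seed=7, grid_step=0.1)
print(f"bootstrap: SE {100*boot.se:.2f} pp, 95% CI {100*boot.ci_low:.1f}-{100*boot.ci_high:.1f}%")
```

prints

```
per-capita: 18.92 g/day, coverage rate: 0.550
shifted mean: 19.91 -> 36.18 g/day, k=0.726, theta=49.87
continuous AAF: 17.0% (survey) -> 27.6% (shifted)
bootstrap: SE 0.78 pp, 95% CI 26.1-29.1%
```

The survey here under-reports by construction (factor 0.529), so the
measured coverage is ≈ 0.55 and the shift scales every drinker mean by
≈ 1/0.55. The shifted male shape k = 0.726 is the structural consequence of
the zero male intercept in the SD regression: for men SD*/mean* is a
constant, so k = (mean*/SD*)² is the same in every male stratum. The AAF
rises by about 11 points after shifting — undercoverage, left uncorrected,
materially understates alcohol-attributable burden.

The same pipeline runs from the shell:

```sh
alcofit simulate --seed 11 --n-per-stratum 1500 --out survey.csv
alcofit shift survey.csv --percapita 8.75
alcofit run config.yaml        # fits, gof, shift, AAF and bootstrap tables + JSON run log
```

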