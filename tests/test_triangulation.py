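"""Per-capita conversion, coverage, and the gamma upshifting procedure."""

import numpy as np
import pytest

from alcofit.distributions import GammaParams
from alcofit.triangulation import (
    SD_SEX_COEF,
    SD_SLOPE,
    ShiftConfig,
    coverage_rate,
    fit_sd_regression,
    percapita_to_grams_per_day,
    predict_shifted_sd,
    shift_distribution,
    shift_mean,
)


class TestPerCapitaConversion:
    def test_us_value(self):
        # 8.75 L/adult/year of pure ethanol at 789.24 g/L over 365 days
        assert percapita_to_grams_per_day(8.75) == pytest.approx(18.92, abs=0.005)

    def test_zero_and_linearity(self):
        assert percapita_to_grams_per_day(0.0) == 0.0
        assert percapita_to_grams_per_day(10.0) == pytest.approx(2 * percapita_to_grams_per_day(5.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            percapita_to_grams_per_day(-1.0)


class TestCoverage:
    def test_exact_reporting_gives_one(self):
        assert coverage_rate(np.full(100, 18.9), 18.9) == pytest.approx(1.0)

    def test_all_abstainers_give_zero(self):
        assert coverage_rate(np.zeros(50), 18.9) == 0.0

    def test_half_underreporting(self, rng):
        x = rng.gamma(0.7, 40, 200_000) * 0.5
        true_mean = 0.7 * 40
        assert coverage_rate(x, true_mean) == pytest.approx(0.5, abs=0.01)

    def test_weighted_mean_used(self):
        x = np.array([0.0, 10.0])
        assert coverage_rate(x, 10.0, weights=[1.0, 3.0]) == pytest.approx(0.75)

    def test_invalid_percapita(self):
        with pytest.raises(ValueError):
            coverage_rate([1.0], 0.0)


class TestShiftMean:
    def test_identity_and_arithmetic(self):
        assert shift_mean(21.0, ShiftConfig(coverage=1.0)) == pytest.approx(21.0)
        assert shift_mean(21.0, ShiftConfig(coverage=0.529)) == pytest.approx(39.70, abs=0.005)
        assert shift_mean(21.0, ShiftConfig(coverage=0.529, target_fraction=0.8)) == pytest.approx(
            31.76, abs=0.005
        )

    def test_same_constant_for_all_strata(self):
        cfg = ShiftConfig(coverage=0.6, target_fraction=0.9)
        means = np.array([5.0, 20.0, 70.0])
        ratios = np.array([shift_mean(m, cfg) for m in means]) / means
        assert np.allclose(ratios, ratios[0])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ShiftConfig(coverage=0.0)
        with pytest.raises(ValueError):
            ShiftConfig(coverage=0.5, target_fraction=1.2)


class TestShiftedSdRegression:
    def test_male_sd_mean_ratio_constant(self, reference_table):
        """For men (sex=0) the predicted SD is proportional to the mean."""
        men = reference_table[reference_table.sex == "men"]
        ratios = men.shifted_sd / men.shifted_mean
        assert ratios.max() - ratios.min() < 1e-4
        assert ratios.mean() == pytest.approx(SD_SLOPE, abs=1e-4)

    def test_female_offset_constant(self, reference_table):
        """For women, SD - slope*mean is one constant across all strata."""
        women = reference_table[reference_table.sex == "women"]
        offsets = women.shifted_sd - SD_SLOPE * women.shifted_mean
        assert offsets.max() - offsets.min() < 2e-3
        assert offsets.mean() == pytest.approx(SD_SEX_COEF, abs=1e-3)

    def test_regression_fit_reproduces_frozen_defaults(self, reference_table):
        slope, sex_coef, r2 = fit_sd_regression(
            reference_table.shifted_mean, reference_table.shifted_sd, reference_table.sex
        )
        assert slope == pytest.approx(SD_SLOPE, abs=1e-6)
        assert sex_coef == pytest.approx(SD_SEX_COEF, abs=1e-6)
        assert r2 > 0.999

    def test_prediction_formula(self):
        cfg = ShiftConfig(coverage=0.5, sd_slope=1.2, sd_sex_coef=0.9)
        assert predict_shifted_sd(10.0, "men", cfg) == pytest.approx(12.0)
        assert predict_shifted_sd(10.0, "women", cfg) == pytest.approx(12.9)
        with pytest.raises(ValueError):
            predict_shifted_sd(-1.0, 0, cfg)


class TestShiftDistribution:
    @pytest.mark.parametrize(
        "mean,sd,k,theta",
        [(40.268, 47.275, 0.726, 55.501), (2.430, 3.856, 0.397, 6.118)],
        ids=["men-white-all", "women-islander-55"],
    )
    def test_published_moment_inversion(self, mean, sd, k, theta):
        p = GammaParams.from_moments(mean, sd)
        assert p.k == pytest.approx(k, abs=1e-3)
        assert p.theta == pytest.approx(theta, abs=1e-3)

    def test_identity_shift(self):
        original = GammaParams(0.5, 40.0)
        cfg = ShiftConfig(
            coverage=1.0, sd_slope=original.sd / original.mean, sd_sex_coef=0.0
        )
        s = shift_distribution(original, "men", cfg)
        assert s.shifted.k == pytest.approx(original.k, rel=1e-10)
        assert s.shifted.theta == pytest.approx(original.theta, rel=1e-10)

    def test_mean_conservation(self):
        cfg = ShiftConfig(coverage=0.529)
        s = shift_distribution(GammaParams(0.436, 48.132), "women", cfg)
        assert s.shifted.mean == pytest.approx(s.shifted_mean, rel=1e-10)
        assert s.shifted.sd == pytest.approx(s.shifted_sd, rel=1e-10)

    def test_lower_coverage_raises_exposure(self):
        original = GammaParams(0.436, 48.132)
        shifts = [
            shift_distribution(original, "men", ShiftConfig(coverage=c)) for c in (0.8, 0.6, 0.4)
        ]
        means = [s.shifted_mean for s in shifts]
        sds = [s.shifted_sd for s in shifts]
        thetas = [s.shifted.theta for s in shifts]
        ks = [s.shifted.k for s in shifts]
        assert means == sorted(means) and means[0] < means[-1]
        assert sds == sorted(sds) and thetas == sorted(thetas)
        # male shifted k depends only on the slope, not on coverage
        assert max(ks) - min(ks) < 1e-12

    def test_non_gamma_rejected(self):
        from alcofit.distributions import fit_mle

        x = np.random.default_rng(3).gamma(0.6, 30, 200)
        weibull = fit_mle(x, "weibull")
        with pytest.raises(ValueError, match="gamma"):
            shift_distribution(weibull, "men", ShiftConfig(coverage=0.5))


def test_population_level_closure(rng):
    """Stratum-weighted shifted drinker totals reproduce target x per-capita exactly."""
    from alcofit.synthetic_data import STATUS_CURRENT, default_specs, generate_survey

    specs = default_specs(n_per_stratum=800)
    survey = generate_survey(specs, seed=11)
    percapita = 20.0
    coverage = coverage_rate(survey["grams_per_day"], percapita)
    for target in (1.0, 0.8):
        cfg = ShiftConfig(coverage=coverage, target_fraction=target)
        total = 0.0
        for _, group in survey.groupby(["sex", "ethnicity", "age_group"]):
            drinkers = group.loc[group["status"] == STATUS_CURRENT, "grams_per_day"]
            share = len(group) / len(survey)
            total += share * (len(drinkers) / len(group)) * shift_mean(drinkers.mean(), cfg)
        assert total == pytest.approx(target * percapita, rel=1e-6)
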