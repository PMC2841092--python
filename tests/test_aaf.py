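"""Attributable fractions: quadrature, continuous and categorical forms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alcofit.aaf import (
    CategoryScheme,
    PopulationStructure,
    RiskFunction,
    aaf_categorical,
    aaf_continuous,
    english_bounds,
    integrate_trapezoid,
)
from alcofit.distributions import GammaParams, LogNormalParams, density


class TestTrapezoid:
    def test_exact_for_linear(self):
        for n in (1, 3, 10):
            assert integrate_trapezoid(lambda x: x, 0.0, 1.0, n) == pytest.approx(0.5, rel=1e-14)

    def test_gamma_density_normalizes(self):
        p = GammaParams(2.0, 1.0)
        val = integrate_trapezoid(lambda x: density(p, np.maximum(x, 1e-300)), 1e-12, 50.0, 100_000)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_second_order_convergence(self):
        exact = 1.0 / 3.0
        e1 = abs(integrate_trapezoid(lambda x: x**2, 0, 1, 100) - exact)
        e2 = abs(integrate_trapezoid(lambda x: x**2, 0, 1, 200) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.05)

    def test_errors(self):
        with pytest.raises(ValueError):
            integrate_trapezoid(lambda x: x, 1.0, 0.0, 10)
        with pytest.raises(ValueError, match="not finite"):
            integrate_trapezoid(lambda x: 1.0 / (x - 0.5), 0.0, 1.0, 10)


class TestPopulationStructure:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PopulationStructure(0.5, 0.2, 0.2)
        with pytest.raises(ValueError):
            PopulationStructure(-0.1, 0.5, 0.6)


class TestContinuousAAF:
    def test_no_excess_risk_gives_zero(self):
        pop = PopulationStructure(0.3, 0.2, 0.5)
        res = aaf_continuous(pop, RiskFunction.constant(1.0, rr_former=1.0), GammaParams(0.7, 50))
        assert res.aaf == pytest.approx(0.0, abs=1e-12)

    def test_levin_closed_form(self):
        pop = PopulationStructure(0.5, 0.0, 0.5)
        res = aaf_continuous(pop, RiskFunction.constant(2.0), GammaParams(0.726, 55.5))
        assert res.aaf == pytest.approx(1.0 / 3.0, abs=1e-8)

    def test_linear_rr_closed_form(self):
        """RR = 1 + x/theta with all current drinkers gives AAF = k/(1+k) analytically."""
        k, theta = 0.726, 55.501
        pop = PopulationStructure(0.0, 0.0, 1.0)
        risk = RiskFunction.linear(1.0 / theta)
        res = aaf_continuous(pop, risk, GammaParams(k, theta), upper=1500.0)
        assert res.aaf == pytest.approx(k / (1 + k), abs=1e-4)

    def test_former_drinker_term(self):
        pop = PopulationStructure(0.5, 0.5, 0.0)
        res = aaf_continuous(pop, RiskFunction.constant(1.0, rr_former=3.0), GammaParams(1, 10))
        assert res.aaf == pytest.approx(0.5 * 2 / (1 + 0.5 * 2), rel=1e-12)

    def test_monotone_in_rr(self):
        pop = PopulationStructure(0.2, 0.1, 0.7)
        dist = GammaParams(0.726, 55.5)
        aafs = [
            aaf_continuous(pop, RiskFunction.loglinear(b, rr_former=1.2), dist, grid_step=0.05).aaf
            for b in (0.002, 0.005, 0.01)
        ]
        assert aafs == sorted(aafs) and aafs[0] < aafs[-1]

    def test_upshifting_never_decreases_convex_rr_aaf(self):
        """The shifted (higher mean and SD) gamma yields at least the original AAF."""
        pop = PopulationStructure(0.2, 0.1, 0.7)
        original = GammaParams(0.436, 48.132)
        shifted = GammaParams(0.726, 55.501)
        risk = RiskFunction.loglinear(0.008, rr_former=1.4)
        a0 = aaf_continuous(pop, risk, original, grid_step=0.05).aaf
        a1 = aaf_continuous(pop, risk, shifted, grid_step=0.05).aaf
        assert a1 >= a0

    def test_cap_monotonicity(self):
        pop = PopulationStructure(0.2, 0.1, 0.7)
        dist = GammaParams(0.726, 55.5)
        risk = RiskFunction.loglinear(0.008)
        capped = aaf_continuous(pop, risk, dist, cap=150.0, grid_step=0.05).aaf
        uncapped = aaf_continuous(pop, risk, dist, grid_step=0.05).aaf
        assert capped <= uncapped

    def test_truncation_mode_below_retention_mode(self):
        pop = PopulationStructure(0.0, 0.0, 1.0)
        dist = GammaParams(0.726, 55.5)
        risk = RiskFunction.loglinear(0.008)
        retained = aaf_continuous(pop, risk, dist, cap=100.0, grid_step=0.05).aaf
        truncated = aaf_continuous(pop, risk, dist, cap=100.0, truncate_above_cap=True, grid_step=0.05).aaf
        assert truncated < retained

    def test_vanishing_exposed_population(self):
        pop = PopulationStructure(1.0, 0.0, 0.0)
        res = aaf_continuous(pop, RiskFunction.loglinear(0.01, rr_former=2.0), GammaParams(1, 30))
        assert res.aaf == 0.0

    def test_nonpositive_rr_rejected(self):
        pop = PopulationStructure(0.2, 0.0, 0.8)
        bad = RiskFunction(lambda x: 1.0 - 0.1 * np.asarray(x), 1.0)
        with pytest.raises(ValueError, match="positive"):
            aaf_continuous(pop, bad, GammaParams(1, 30), grid_step=0.1)

    def test_works_for_lognormal_exposure(self):
        pop = PopulationStructure(0.3, 0.0, 0.7)
        res = aaf_continuous(pop, RiskFunction.constant(2.0), LogNormalParams(2.0, 1.0), grid_step=0.05, upper=2000.0)
        assert res.aaf == pytest.approx(0.7 / 1.7, abs=1e-4)


class TestCategoricalAAF:
    def _scheme(self, rrs=(1.3, 2.0, 3.5), rr_former=1.2):
        return CategoryScheme(bounds=english_bounds("men"), rrs=rrs, rr_former=rr_former)

    def test_unit_rrs_give_zero(self):
        pop = PopulationStructure(0.3, 0.2, 0.5)
        scheme = self._scheme(rrs=(1.0, 1.0, 1.0), rr_former=1.0)
        assert aaf_categorical(pop, scheme, GammaParams(0.7, 40)).aaf == 0.0

    def test_single_category_matches_levin(self):
        pop = PopulationStructure(0.4, 0.0, 0.6)
        scheme = CategoryScheme(bounds=((0.0, math.inf),), rrs=(2.0,))
        res = aaf_categorical(pop, scheme, GammaParams(0.7, 40))
        assert res.aaf == pytest.approx(0.6 / 1.6, rel=1e-12)

    def test_step_rr_matches_continuous(self):
        """Continuous AAF with the scheme's own step RR equals the categorical AAF."""
        pop = PopulationStructure(0.25, 0.15, 0.6)
        dist = GammaParams(0.726, 55.501)
        scheme = self._scheme()
        cat = aaf_categorical(pop, scheme, dist).aaf
        cont = aaf_continuous(pop, scheme.to_risk_function(), dist).aaf
        assert cont == pytest.approx(cat, abs=1e-6)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            CategoryScheme(bounds=((0.0, 40.0), (50.0, math.inf)), rrs=(1.0, 2.0))
        with pytest.raises(ValueError):
            CategoryScheme(bounds=((0.0, 40.0),), rrs=(2.0,))
        with pytest.raises(ValueError):
            CategoryScheme(bounds=((10.0, math.inf),), rrs=(2.0,))


@given(
    p_cur=st.floats(0.05, 0.95),
    rr=st.floats(1.0, 8.0),
)
def test_constant_rr_always_levin(p_cur, rr):
    pop = PopulationStructure(1.0 - p_cur, 0.0, p_cur)
    res = aaf_continuous(pop, RiskFunction.constant(rr), GammaParams(0.7, 30), grid_step=0.5)
    expected = p_cur * (rr - 1) / (1 + p_cur * (rr - 1))
    assert res.aaf == pytest.approx(expected, abs=1e-10)
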