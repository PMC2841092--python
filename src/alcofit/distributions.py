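"""Parametric models of daily ethanol intake among current drinkers.

Three right-skewed two-parameter families are supported — log-normal,
gamma, and Weibull — on the support (0, inf) grams of pure ethanol per
day.  The module provides densities, CDFs, moment conversions, and
maximum-likelihood fitting with optional frequency-style survey weights.

The gamma family plays a special role downstream: its MLE preserves the
sample mean exactly (theta_hat = xbar / k_hat at the stationary point),
which is what makes the per-capita upshifting procedure in
:mod:`alcofit.triangulation` consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaParams",
    "LogNormalParams",
    "WeibullParams",
    "FittedModel",
    "ConvergenceError",
    "FAMILIES",
    "density",
    "cdf",
    "fit_mle",
    "method_of_moments",
    "log_likelihood",
]

FAMILIES = ("gamma", "lognormal", "weibull")

#: default relative-change tolerance for Newton-Raphson fitting
DEFAULT_TOL = 1e-8
#: default iteration cap for Newton-Raphson fitting
DEFAULT_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """Raised when an MLE optimisation cannot converge (e.g. degenerate data)."""


@dataclass(frozen=True)
class GammaParams:
    """Gamma family: shape ``k`` (dimensionless), scale ``theta`` (g/day).

    mean = k * theta, variance = k * theta**2.
    """

    k: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"gamma shape k must be positive and finite, got {self.k}")
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError(f"gamma scale theta must be positive and finite, got {self.theta}")

    @property
    def mean(self) -> float:
        return self.k * self.theta

    @property
    def sd(self) -> float:
        return math.sqrt(self.k) * self.theta

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "GammaParams":
        """Moment inversion: k = (mean/SD)^2, theta = SD^2/mean."""
        if not (mean > 0 and sd > 0):
            raise ValueError("mean and sd must be positive")
        return cls(k=(mean / sd) ** 2, theta=sd**2 / mean)

    @property
    def frozen(self):
        return stats.gamma(a=self.k, scale=self.theta)


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal family: log-consumption is Normal(mu, sigma**2)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"lognormal mu must be finite, got {self.mu}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"lognormal sigma must be positive and finite, got {self.sigma}")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    @property
    def frozen(self):
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))


@dataclass(frozen=True)
class WeibullParams:
    """Weibull family: shape ``gamma_shape`` (dimensionless), scale ``theta`` (g/day)."""

    gamma_shape: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.gamma_shape > 0 and math.isfinite(self.gamma_shape)):
            raise ValueError(f"weibull shape must be positive and finite, got {self.gamma_shape}")
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError(f"weibull scale must be positive and finite, got {self.theta}")

    @property
    def mean(self) -> float:
        return self.theta * math.gamma(1 + 1 / self.gamma_shape)

    @property
    def sd(self) -> float:
        g1 = math.gamma(1 + 1 / self.gamma_shape)
        g2 = math.gamma(1 + 2 / self.gamma_shape)
        return self.theta * math.sqrt(g2 - g1**2)

    @property
    def frozen(self):
        return stats.weibull_min(c=self.gamma_shape, scale=self.theta)


FamilyParams = Union[GammaParams, LogNormalParams, WeibullParams]

_FAMILY_OF_TYPE = {
    GammaParams: "gamma",
    LogNormalParams: "lognormal",
    WeibullParams: "weibull",
}


def family_of(params: FamilyParams) -> str:
    try:
        return _FAMILY_OF_TYPE[type(params)]
    except KeyError:
        raise TypeError(f"not a known family parameter type: {type(params)!r}") from None


@dataclass(frozen=True)
class FittedModel:
    """A fitted family with bookkeeping: family name, params, n, log-likelihood."""

    family: str
    params: FamilyParams
    n_obs: int
    loglik: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_obs < 2:
            raise ValueError("a fitted model needs at least 2 observations")
        if not math.isfinite(self.loglik):
            raise ValueError("log-likelihood at the optimum must be finite")


def density(params: FamilyParams, x) -> np.ndarray | float:
    """Probability density (per g/day) at consumption ``x`` > 0."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0) or not np.all(np.isfinite(x_arr)):
        raise ValueError("density is defined for finite x > 0 only")
    out = params.frozen.pdf(x_arr)
    return out if out.ndim else float(out)


def cdf(params: FamilyParams, x) -> np.ndarray | float:
    """Cumulative probability of consuming at most ``x`` g/day (x >= 0)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(np.isnan(x_arr)):
        raise ValueError("cdf is defined for x >= 0 only")
    out = params.frozen.cdf(x_arr)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _prepare(volumes, weights):
    x = np.asarray(volumes, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d array of at least 2 consumption values")
    if not np.all(np.isfinite(x)):
        raise ValueError("volumes must be finite; drop missing values before fitting")
    if np.any(x <= 0):
        raise ValueError(
            "non-positive volumes are outside the support (0, inf); "
            "reclassify zero reporters as abstainers before fitting"
        )
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive, finite, and match volumes in shape")
    return x, w


def log_likelihood(params: FamilyParams, volumes, weights=None) -> float:
    """(Weighted) log-likelihood of ``volumes`` under ``params``."""
    x, w = _prepare(volumes, weights)
    return float(np.sum(w * params.frozen.logpdf(x)))


def method_of_moments(volumes, family: str, weights=None) -> FamilyParams:
    """Moment-matched parameters; used to initialise Newton-Raphson."""
    x, w = _prepare(volumes, weights)
    wsum = w.sum()
    m = float(np.sum(w * x) / wsum)
    v = float(np.sum(w * (x - m) ** 2) / wsum)
    if v <= 0:
        raise ConvergenceError("zero sample variance: moment matching is degenerate")
    s = math.sqrt(v)
    if family == "gamma":
        return GammaParams.from_moments(m, s)
    if family == "lognormal":
        sigma2 = math.log1p(v / m**2)
        return LogNormalParams(mu=math.log(m) - sigma2 / 2, sigma=math.sqrt(sigma2))
    if family == "weibull":
        # standard CV-based approximation for the shape; adequate as an initial value
        shape = (s / m) ** -1.086
        theta = m / math.gamma(1 + 1 / shape)
        return WeibullParams(gamma_shape=shape, theta=theta)
    raise ValueError(f"unknown family {family!r}")


def _fit_gamma(x, w, tol, max_iter) -> GammaParams:
    """Profile Newton-Raphson on the shape.

    Given k, the scale MLE is theta = xbar/k, so the score reduces to
    log k - digamma(k) = log(xbar) - mean(log x); Newton steps on that
    scalar equation converge quadratically.  The fitted mean k*theta
    therefore equals the weighted sample mean exactly.
    """
    wsum = w.sum()
    xbar = float(np.sum(w * x) / wsum)
    logbar = float(np.sum(w * np.log(x)) / wsum)
    s = math.log(xbar) - logbar
    if s <= 0:  # equality holds only when all x identical (Jensen)
        raise ConvergenceError("zero variance in volumes: gamma MLE does not exist")
    k = method_of_moments(x, "gamma", w).k
    for _ in range(max_iter):
        f = math.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) <= tol * abs(k):
            k = k_new
            break
        k = k_new
    else:
        raise ConvergenceError(f"gamma shape update did not converge in {max_iter} iterations")
    return GammaParams(k=k, theta=xbar / k)


def _fit_lognormal(x, w) -> LogNormalParams:
    # closed-form MLE: mu = weighted mean of log x, sigma = weighted SD of log x
    wsum = w.sum()
    lx = np.log(x)
    mu = float(np.sum(w * lx) / wsum)
    sigma2 = float(np.sum(w * (lx - mu) ** 2) / wsum)
    if sigma2 <= 0:
        raise ConvergenceError("zero variance in log-volumes: log-normal MLE is degenerate")
    return LogNormalParams(mu=mu, sigma=math.sqrt(sigma2))


def _fit_weibull(x, w, tol, max_iter) -> WeibullParams:
    """Profile Newton-Raphson on the Weibull shape.

    Given the shape g, theta^g = weighted mean of x^g; the profile score is
    h(g) = sum(w x^g log x)/sum(w x^g) - 1/g - mean_w(log x) = 0.
    Falls back to a bounded bisection if a Newton step leaves the domain.
    """
    wsum = w.sum()
    lx = np.log(x)
    logbar = float(np.sum(w * lx) / wsum)

    def score_and_slope(g):
        xg = np.power(x, g)
        a = float(np.sum(w * xg))
        b = float(np.sum(w * xg * lx))
        c = float(np.sum(w * xg * lx * lx))
        h = b / a - 1.0 / g - logbar
        hp = (c * a - b * b) / a**2 + 1.0 / g**2
        return h, hp

    g = method_of_moments(x, "weibull", w).gamma_shape
    for _ in range(max_iter):
        h, hp = score_and_slope(g)
        g_new = g - h / hp
        if not (g_new > 0 and math.isfinite(g_new)):
            g_new = g / 2.0 if h < 0 else g * 2.0
        if abs(g_new - g) <= tol * abs(g):
            g = g_new
            break
        g = g_new
    else:
        raise ConvergenceError(f"weibull shape update did not converge in {max_iter} iterations")
    theta = float(np.sum(w * np.power(x, g)) / wsum) ** (1.0 / g)
    return WeibullParams(gamma_shape=g, theta=theta)


def fit_mle(
    volumes,
    family: str,
    weights=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FittedModel:
    """Maximum-likelihood fit of one family to strictly positive volumes.

    Parameters
    ----------
    volumes
        Grams of ethanol per day among current drinkers, all > 0, n >= 2.
    family
        ``"gamma"``, ``"lognormal"`` or ``"weibull"``.
    weights
        Optional positive frequency-style weights (default: all 1).
    tol, max_iter
        Relative-change convergence tolerance and iteration cap for the
        Newton-Raphson updates (gamma and Weibull shapes; log-normal is
        closed form).

    Raises
    ------
    ValueError
        Non-positive or non-finite volumes, bad weights, unknown family.
    ConvergenceError
        Degenerate data (zero variance) or failure to converge.
    """
    x, w = _prepare(volumes, weights)
    if np.all(x == x[0]):
        raise ConvergenceError("all volumes identical: no two-parameter family can be fitted")
    if family == "gamma":
        params: FamilyParams = _fit_gamma(x, w, tol, max_iter)
    elif family == "lognormal":
        params = _fit_lognormal(x, w)
    elif family == "weibull":
        params = _fit_weibull(x, w, tol, max_iter)
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return FittedModel(
        family=family,
        params=params,
        n_obs=int(x.size),
        loglik=log_likelihood(params, x, w),
    )
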