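"""Bootstrap standard errors and percentile confidence intervals for AAFs.

The resampling unit is the respondent: each replicate redraws the stratum's
respondents with replacement, recomputes the abstention proportions, refits
the drinker gamma, reapplies the per-capita shift, and recomputes the AAF.
The coverage constant and the shifted-SD regression coefficients are held
fixed across replicates — they come from external totals and a separate
calibration, not from the stratum being resampled.

For the shifted AAF the gamma refit enters only through the drinker mean
(the gamma MLE preserves the sample mean, and the shifted SD is a function
of the shifted mean), so replicates remain well defined even when a
resample has zero drinker variance.  Bootstrapping the *original* fitted
distribution's AAF does require a full refit; zero-variance resamples are
then dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaf import PopulationStructure, RiskFunction, aaf_continuous
from .distributions import ConvergenceError, GammaParams, fit_mle
from .synthetic_data import STATUS_ABSTAINER, STATUS_CURRENT, STATUS_FORMER
from .triangulation import ShiftConfig, predict_shifted_sd, shift_mean

__all__ = ["BootstrapResult", "bootstrap_aaf"]

#: minimum stratum size for a meaningful nonparametric bootstrap
MIN_STRATUM_N = 30
#: abort when more than this fraction of replicates had to be dropped
MAX_DROP_FRACTION = 0.01


@dataclass(frozen=True)
class BootstrapResult:
    """Point AAF with bootstrap SE and 95% percentile interval."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int
    n_dropped: int
    replicates: np.ndarray

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error cannot be negative")
        if not self.ci_low <= self.ci_high:
            raise ValueError("interval bounds out of order")


def _stratum_aaf(
    p_form: float,
    p_cur: float,
    volumes: np.ndarray,
    sex,
    risk: RiskFunction,
    config: ShiftConfig,
    target: str,
    cap,
    grid_step: float,
    upper: float,
) -> float:
    pop = PopulationStructure(p_abs=1.0 - p_form - p_cur, p_form=p_form, p_cur=p_cur)
    if target == "shifted":
        mean = shift_mean(float(volumes.mean()), config)
        sd = predict_shifted_sd(mean, sex, config)
        dist = GammaParams.from_moments(mean, sd)
    else:
        dist = fit_mle(volumes, "gamma").params
    return aaf_continuous(pop, risk, dist, cap=cap, grid_step=grid_step, upper=upper).aaf


def bootstrap_aaf(
    records: pd.DataFrame,
    risk: RiskFunction,
    config: ShiftConfig,
    n_reps: int = 10_000,
    seed: int | None = None,
    target: str = "shifted",
    cap: float | None = None,
    grid_step: float = 0.01,
    upper: float = 300.0,
) -> BootstrapResult:
    """Nonparametric bootstrap of one stratum's AAF.

    Parameters
    ----------
    records
        One stratum's survey records with ``sex``, ``status`` and
        ``grams_per_day`` columns (at least :data:`MIN_STRATUM_N` rows).
    risk
        Relative-risk inputs for the AAF.
    config
        Shift configuration; coverage and SD coefficients are treated as
        fixed external constants across replicates.
    n_reps, seed
        Number of replicates (10,000 by default) and the mandatory RNG
        seed; replicate r draws from spawned substream r, so results are
        reproducible bit for bit and independent of evaluation order.
    target
        ``"shifted"`` (default) bootstraps the upshifted AAF; ``"original"``
        the AAF of the unshifted fitted gamma.
    cap, grid_step, upper
        Forwarded to :func:`alcofit.aaf.aaf_continuous`.

    Raises
    ------
    ValueError
        Stratum too small, missing seed, or unusable inputs.
    RuntimeError
        More than 1% of replicates dropped (all-abstainer or unfittable).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for the bootstrap")
    if target not in ("shifted", "original"):
        raise ValueError("target must be 'shifted' or 'original'")
    n = len(records)
    if n < MIN_STRATUM_N:
        raise ValueError(f"stratum has {n} respondents; need at least {MIN_STRATUM_N}")
    sexes = records["sex"].unique()
    if len(sexes) != 1:
        raise ValueError("bootstrap strata must be single-sex (the SD regression needs one code)")
    sex = sexes[0]

    status = records["status"].to_numpy()
    is_cur = status == STATUS_CURRENT
    is_form = status == STATUS_FORMER
    volumes = records["grams_per_day"].to_numpy(dtype=float)
    if not is_cur.any():
        raise ValueError("stratum has no current drinkers")

    point = _stratum_aaf(
        float(is_form.mean()), float(is_cur.mean()), volumes[is_cur],
        sex, risk, config, target, cap, grid_step, upper,
    )

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    estimates = np.empty(n_reps)
    kept = 0
    dropped = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        idx = rng.integers(0, n, n)
        cur = is_cur[idx]
        n_cur = int(cur.sum())
        if n_cur == 0:
            dropped += 1
            continue
        v = volumes[idx][cur]
        try:
            estimates[kept] = _stratum_aaf(
                float(is_form[idx].mean()), n_cur / n, v,
                sex, risk, config, target, cap, grid_step, upper,
            )
        except ConvergenceError:
            dropped += 1
            continue
        kept += 1
    if dropped > MAX_DROP_FRACTION * n_reps:
        raise RuntimeError(
            f"{dropped} of {n_reps} bootstrap replicates dropped "
            "(all-abstainer or degenerate resamples); stratum too sparse to bootstrap"
        )
    reps = estimates[:kept]
    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    spread = float(np.ptp(reps)) if kept else 0.0
    return BootstrapResult(
        point=point,
        # identical replicates mean exactly zero spread; avoid summation noise in std
        se=float(reps.std(ddof=1)) if kept > 1 and spread > 0 else 0.0,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_reps=n_reps,
        seed=seed,
        n_dropped=dropped,
        replicates=reps,
    )
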