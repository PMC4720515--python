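"""Demographic analysis of lifespan cohorts.

The Gompertz law of mortality models the hazard (instantaneous death rate)
as an exponential function of age,

    h(t) = A * exp(G * t),

with baseline hazard A (1/day) and rate-of-aging G (1/day).  Its survival
function is S(t) = exp(-(A/G) * (exp(G*t) - 1)); G -> 0 degenerates to the
exponential (memoryless) distribution with hazard A.  Two cohorts that age
at the same rate G but differ by a time offset show parallel log-mortality
curves — the signature of a treatment that delays aging rather than slowing
its rate.

This module estimates empirical mortality curves from life tables, fits the
Gompertz model by maximum likelihood (with right-censoring), simulates
cohorts from it, compares survival curves with the Mantel-Haenszel log-rank
test, and estimates the Monte-Carlo power of a lifespan experiment to detect
an additive lifespan extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.integrate
import scipy.optimize
import scipy.special
import scipy.stats
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.proportion import proportion_confint

from .io import DataError, LifeTable


class FitError(RuntimeError):
    """Model fitting failed to converge."""


@dataclass
class GompertzModel:
    """Gompertz hazard h(t) = A * exp(G * t); rates in 1/day."""

    A: float
    G: float
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.A <= 0 or self.G < 0:
            raise ValueError("require A > 0 and G >= 0")

    def hazard(self, t):
        return self.A * np.exp(self.G * np.asarray(t, float))

    def cumulative_hazard(self, t):
        t = np.asarray(t, float)
        if self.G == 0:
            return self.A * t
        return (self.A / self.G) * np.expm1(self.G * t)

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def ppf(self, q):
        """Inverse CDF: the age by which a fraction q of the cohort has died."""
        q = np.asarray(q, float)
        if self.G == 0:
            return -np.log1p(-q) / self.A
        return np.log1p(-(self.G / self.A) * np.log1p(-q)) / self.G

    def mean_lifespan(self) -> float:
        """E[T] = (1/G) * exp(A/G) * E1(A/G), the exponential-integral form."""
        if self.G == 0:
            return 1.0 / self.A
        x = self.A / self.G
        if x > 1e-12:
            return float(np.exp(x) * scipy.special.exp1(x) / self.G)
        return float(scipy.integrate.quad(self.survival, 0, np.inf)[0])

    @classmethod
    def from_mean_lifespan(cls, mean_days: float, G: float) -> "GompertzModel":
        """Choose A so the model's mean lifespan equals ``mean_days`` at rate G."""
        if mean_days <= 0:
            raise ValueError("mean lifespan must be positive")
        if G == 0:
            return cls(A=1.0 / mean_days, G=0.0)

        def gap(log_a: float) -> float:
            return cls(A=math.exp(log_a), G=G).mean_lifespan() - mean_days

        log_a = scipy.optimize.brentq(gap, math.log(1e-12), math.log(10.0))
        return cls(A=math.exp(log_a), G=G, fit_meta={"method": "from_mean_lifespan"})


@dataclass
class MortalityCurve:
    """Interval hazard estimates on the scoring grid of a life table."""

    day: np.ndarray
    hazard: np.ndarray  # deaths per animal-day, smoothed
    raw_hazard: np.ndarray
    window_days: float

    @property
    def log_hazard(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.hazard > 0, np.log(self.hazard), np.nan)


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


@dataclass
class PowerResult:
    effect_days: float
    n_per_arm: int
    alpha: float
    n_reps: int
    power: float
    mc_ci95: tuple[float, float]
    seed: int | None = None


def estimate_mortality(lt: LifeTable, window_days: float = 3.0) -> MortalityCurve:
    """Empirical interval hazard from a life table, moving-average smoothed.

    Scoring intervals are taken from the recorded event days themselves (the
    grid on which the cohort was actually scored).  Interval hazard is
    deaths / animal-days at risk in the interval; the smoothed curve is a
    centered moving average over a ``window_days``-wide window on the day
    axis, so a window no wider than the scoring interval is the identity.
    """
    if not lt.death_days:
        raise DataError(f"cohort {lt.cohort_id!r} has no death events")
    days = np.asarray(sorted(set(lt.death_days) | set(lt.censored_days)), float)
    deaths = np.asarray([lt.death_days.count(d) for d in days], float)
    censored = np.asarray([lt.censored_days.count(d) for d in days], float)
    at_risk = lt.n_total - np.concatenate([[0.0], np.cumsum(deaths + censored)[:-1]])
    widths = np.diff(np.concatenate([[0.0], days]))
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = deaths / (at_risk * widths)
    raw = np.nan_to_num(raw, nan=0.0, posinf=0.0)
    smoothed = np.empty_like(raw)
    half = window_days / 2.0
    for i, d in enumerate(days):
        sel = np.abs(days - d) <= half
        smoothed[i] = raw[sel].mean()
    return MortalityCurve(day=days, hazard=smoothed, raw_hazard=raw, window_days=window_days)


def _gompertz_negloglik(params: np.ndarray, t_death, t_cens) -> float:
    log_a, log_g = params
    a, g = math.exp(log_a), math.exp(log_g)
    loglik = len(t_death) * log_a + g * t_death.sum()
    loglik -= (a / g) * (np.expm1(g * t_death).sum() + np.expm1(g * t_cens).sum())
    return -loglik


def fit_gompertz(lt: LifeTable) -> GompertzModel:
    """Maximum-likelihood Gompertz fit to death times with right-censoring.

    Parameterized on (log A, log G) so positivity is structural.  Refuses
    life tables with fewer than 20 uncensored deaths — below that the
    likelihood surface is too flat for A and G to separate reliably.
    """
    if len(lt.death_days) < 20:
        raise FitError(
            f"cohort {lt.cohort_id!r}: need >= 20 uncensored deaths, have {len(lt.death_days)}"
        )
    t_death = np.asarray(lt.death_days, float)
    t_cens = np.asarray(lt.censored_days, float)
    mean_t = float(t_death.mean())
    best = None
    for g0 in (0.05, 0.2, 0.5):
        x0 = np.array([math.log(1.0 / max(mean_t, 1e-6)), math.log(g0)])
        res = scipy.optimize.minimize(
            _gompertz_negloglik, x0, args=(t_death, t_cens), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"Gompertz fit did not converge for cohort {lt.cohort_id!r}")
    a, g = math.exp(best.x[0]), math.exp(best.x[1])
    return GompertzModel(
        A=a,
        G=g,
        fit_meta={
            "method": "mle",
            "n_animals": lt.n_total,
            "n_deaths": len(lt.death_days),
            "log_likelihood": -float(best.fun),
        },
    )


def simulate_cohort(
    model: GompertzModel,
    n: int,
    shift_days: float = 0.0,
    seed: int | np.random.Generator | None = None,
    cohort_id: str = "sim",
) -> LifeTable:
    """Draw n death times from the model by inverse-CDF sampling, then apply
    an additive day-shift (floored at 0) emulating a delayed-aging treatment."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = model.ppf(rng.uniform(size=n)) + shift_days
    return LifeTable(cohort_id=cohort_id, death_days=list(np.clip(t, 0.0, None)))


def logrank_test(a: LifeTable, b: LifeTable) -> LogrankResult:
    """Mantel-Haenszel log-rank comparison of two survival curves.

    Observed-minus-expected deaths accumulated over pooled event times with
    the hypergeometric variance (ties supported); two-sided p from the
    chi-square distribution with 1 df.
    """
    if a.n_total == 0 or b.n_total == 0:
        raise DataError("both cohorts must be nonempty")
    if not a.death_days and not b.death_days:
        raise DataError("no death events in either cohort")
    res = _ll_logrank(
        a.durations(), b.durations(),
        event_observed_A=a.event_observed(), event_observed_B=b.event_observed(),
    )
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def power_of_detection(
    model: GompertzModel,
    n_per_arm: int,
    effect_days: float,
    alpha: float = 0.01,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PowerResult:
    """Monte-Carlo power of the log-rank test to detect an additive lifespan
    extension of ``effect_days`` with ``n_per_arm`` animals per arm.

    Each replicate simulates a control cohort and a day-shifted treated
    cohort from the same Gompertz model and applies the Mantel-Haenszel
    log-rank test; power is the fraction of replicates with two-sided
    p < alpha, with a Wilson 95% interval for the Monte-Carlo error.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a usable power estimate")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        ctrl = simulate_cohort(model, n_per_arm, 0.0, rng, "control")
        trt = simulate_cohort(model, n_per_arm, effect_days, rng, "treated")
        if logrank_test(ctrl, trt).p_value < alpha:
            hits += 1
    lo, hi = proportion_confint(hits, n_reps, alpha=0.05, method="wilson")
    return PowerResult(
        effect_days=effect_days,
        n_per_arm=n_per_arm,
        alpha=alpha,
        n_reps=n_reps,
        power=hits / n_reps,
        mc_ci95=(float(lo), float(hi)),
        seed=seed,
    )
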