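"""Parametric survival laws, censored maximum likelihood and model selection.

Five families are supported, all with a positive ``scale`` and ``shape`` and
time measured in months.  The Weibull parameterization is the one the source
decision model prints (cumulative hazard ``scale * t**shape``), and the other
families follow the standard survival-analysis forms expressed in the same
two-parameter style:

========== ============================================== ==================
family     survivor function S(t)                         shape meaning
========== ============================================== ==================
exponential ``exp(-scale * t)``                           fixed at 1
weibull     ``exp(-scale * t**shape)``                    hazard power
loglogistic ``1 / (1 + scale * t**shape)``                odds power
lognormal   ``1 - Phi((log t - log scale) / shape)``      sigma of log-time
gompertz    ``exp(-(scale/shape) * (exp(shape*t) - 1))``  log-hazard slope
========== ============================================== ==================

For the lognormal, ``scale`` is the median survival time; for the Gompertz,
the shape is restricted to be positive (increasing hazard), which is the
regime relevant to extrapolating progression and death in advanced cancer.

Fitting maximises the right-censored log-likelihood

    sum_events log f(t_i) + sum_censored log S(t_i)

over log-transformed parameters (unconstrained optimisation with positivity
built in), multi-started from method-of-moments style initial values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

from .errors import DegenerateDataError, FitConvergenceError

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class SurvivalSpec:
    """A parametric time-to-event law (family + scale/shape), time in months."""

    family: str
    scale: float
    shape: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown survival family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be a positive finite real, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be a positive finite real, got {self.shape}")
        if self.family == "exponential" and self.shape != 1.0:
            raise ValueError("exponential law has shape fixed at 1")


@dataclass(frozen=True)
class IPDRecord:
    """One pseudo individual-patient observation: time (months) and event flag."""

    time: float
    event: bool

    def __post_init__(self):
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"time must be positive and finite, got {self.time}")


@dataclass(frozen=True)
class FittedModel:
    """A fitted parametric law with its log-likelihood and information criteria."""

    spec: SurvivalSpec
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    converged: bool = True


# ---------------------------------------------------------------------------
# closed-form survivor / density / quantile per family
# ---------------------------------------------------------------------------

def _log_survival(t, family, scale, shape):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return -scale * t
    if family == "weibull":
        return -scale * np.power(t, shape)
    if family == "loglogistic":
        return -np.log1p(scale * np.power(t, shape))
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(np.where(t > 0, t, 1.0)) - math.log(scale)) / shape
        out = special.log_ndtr(-z)
        return np.where(t > 0, out, 0.0)
    if family == "gompertz":
        with np.errstate(over="ignore"):  # deep-tail exp overflow -> S = 0
            return -(scale / shape) * np.expm1(shape * t)
    raise ValueError(family)


def _log_density(t, family, scale, shape):
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    if family == "exponential":
        return math.log(scale) - scale * t
    if family == "weibull":
        return (
            math.log(scale) + math.log(shape) + (shape - 1.0) * logt
            - scale * np.power(t, shape)
        )
    if family == "loglogistic":
        u = scale * np.power(t, shape)
        return math.log(scale) + math.log(shape) + (shape - 1.0) * logt - 2.0 * np.log1p(u)
    if family == "lognormal":
        z = (logt - math.log(scale)) / shape
        return -0.5 * z * z - logt - math.log(shape) - 0.5 * math.log(2.0 * math.pi)
    if family == "gompertz":
        return math.log(scale) + shape * t - (scale / shape) * np.expm1(shape * t)
    raise ValueError(family)


def survival_probability(spec: SurvivalSpec, t) -> float | np.ndarray:
    """S(t): probability of being event-free at ``t`` months.

    Vectorised over ``t``; raises for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_probability requires t >= 0")
    out = np.exp(_log_survival(t_arr, spec.family, spec.scale, spec.shape))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def quantile(spec: SurvivalSpec, survival: float) -> float:
    """Invert S: the time at which the survivor function equals ``survival``."""
    u = float(survival)
    if not 0.0 < u < 1.0:
        raise ValueError("survival level must lie strictly in (0, 1)")
    fam, sc, sh = spec.family, spec.scale, spec.shape
    if fam == "exponential":
        return -math.log(u) / sc
    if fam == "weibull":
        return (-math.log(u) / sc) ** (1.0 / sh)
    if fam == "loglogistic":
        return ((1.0 - u) / (u * sc)) ** (1.0 / sh)
    if fam == "lognormal":
        return sc * math.exp(sh * special.ndtri(1.0 - u))
    if fam == "gompertz":
        return math.log1p(-sh * math.log(u) / sc) / sh
    raise ValueError(fam)


def median_survival(spec: SurvivalSpec) -> float:
    """The time t with S(t) = 1/2 (closed form for every family)."""
    return quantile(spec, 0.5)


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

def log_likelihood(spec: SurvivalSpec, ipd: Sequence[IPDRecord]) -> float:
    """Right-censored log-likelihood of a sample under ``spec``."""
    times = np.array([r.time for r in ipd])
    events = np.array([r.event for r in ipd], dtype=bool)
    ll = 0.0
    if events.any():
        ll += float(np.sum(_log_density(times[events], spec.family, spec.scale, spec.shape)))
    if (~events).any():
        ll += float(np.sum(_log_survival(times[~events], spec.family, spec.scale, spec.shape)))
    return ll


def _initial_points(family, times, events):
    """Moment-style multi-start values (scale, shape) for the optimiser."""
    rate = max(events.sum(), 1) / times.sum()  # exponential MLE of the hazard
    med = float(np.median(times))
    if family == "exponential":
        return [(rate, 1.0)]
    if family == "weibull":
        return [
            (rate, 1.0), (_scale_for(med, 0.7), 0.7),
            (_scale_for(med, 1.5), 1.5), (_scale_for(med, 2.5), 2.5),
        ]
    if family == "loglogistic":
        return [(1.0 / med ** sh, sh) for sh in (0.8, 1.5, 3.0)]
    if family == "lognormal":
        logs = np.log(times[events]) if events.any() else np.log(times)
        mu, sigma = float(np.mean(logs)), max(float(np.std(logs)), 0.05)
        return [(math.exp(mu), sigma), (med, 1.0)]
    if family == "gompertz":
        return [(rate, sh) for sh in (1e-3, 0.02, 0.1)]
    raise ValueError(family)


def _scale_for(median, shape):
    """Weibull scale putting the median of the law at ``median`` months."""
    return _LOG2 / median ** shape


def fit_parametric(ipd: Sequence[IPDRecord], family: str) -> FittedModel:
    """Maximum-likelihood fit of one family to right-censored data.

    Requires at least 10 records and at least one observed event.  Parameters
    are optimised on the log scale (positivity for free) from several
    moment-based starting points; the best converged solution is kept.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    ipd = list(ipd)
    if len(ipd) < 10:
        raise DegenerateDataError(
            f"need at least 10 records to fit, got {len(ipd)}"
        )
    times = np.array([r.time for r in ipd])
    events = np.array([r.event for r in ipd], dtype=bool)
    if not events.any():
        raise DegenerateDataError("all records censored: the likelihood has no events")

    n_params = 1 if family == "exponential" else 2

    def nll(theta):
        sc = math.exp(theta[0])
        sh = 1.0 if family == "exponential" else math.exp(theta[1])
        with np.errstate(over="ignore", invalid="ignore"):
            ll = (
                np.sum(_log_density(times[events], family, sc, sh))
                + np.sum(_log_survival(times[~events], family, sc, sh))
            )
        return -ll if np.isfinite(ll) else 1e300

    best = None
    for sc0, sh0 in _initial_points(family, times, events):
        x0 = [math.log(sc0)] if family == "exponential" else [math.log(sc0), math.log(sh0)]
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not best.success or not np.isfinite(best.fun):
        params = None if best is None else np.exp(best.x)
        raise FitConvergenceError(
            f"{family} fit failed to converge",
            last_params=params,
            last_loglik=None if best is None else -best.fun,
        )
    sc = math.exp(best.x[0])
    sh = 1.0 if family == "exponential" else math.exp(best.x[1])
    loglik = -float(best.fun)
    spec = SurvivalSpec(family, sc, sh)
    return FittedModel(
        spec=spec,
        loglik=loglik,
        n_params=n_params,
        n_obs=len(ipd),
        aic=2.0 * n_params - 2.0 * loglik,
        bic=n_params * math.log(len(ipd)) - 2.0 * loglik,
        converged=bool(best.success),
    )


def fit_all_families(ipd: Sequence[IPDRecord]) -> list[FittedModel]:
    """Fit every supported family to the same sample."""
    return [fit_parametric(ipd, fam) for fam in FAMILIES]


def select_best_model(fits: Iterable[FittedModel]) -> FittedModel:
    """Minimum-AIC fit; ties broken by BIC, then by parsimony."""
    fits = list(fits)
    if not fits:
        raise ValueError("select_best_model requires at least one fitted model")
    return min(fits, key=lambda f: (f.aic, f.bic, f.n_params))
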