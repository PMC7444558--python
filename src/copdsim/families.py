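"""Parametric survival families in a uniform accelerated-failure-time form.

All six families used for the transition models — exponential, Weibull,
log-normal, log-logistic, gamma and generalized gamma — are expressed with a
*location* on the log-time scale, an optional positive *scale*, and an
optional extra *shape*.  Covariates act on the location only: a linear
predictor ``x . beta`` added to the location multiplies every quantile of the
event-time distribution by ``exp(x . beta)`` (the AFT property), which makes
family swapping transparent to everything downstream.

Parameter conventions (``t`` in days, ``z = (log t - location) / scale``):

==================  =====================================================
exponential         S(t) = exp(-t * exp(-location)); rate = exp(-location)
weibull             S(t) = exp(-(t * exp(-location))**(1/scale))
lognormal           S(t) = 1 - Phi(z)
loglogistic         S(t) = 1 / (1 + (t * exp(-location))**(1/scale))
gamma               S(t) = Q(a, a*t*exp(-location)), a = shape
                    (mean event time is exp(location))
generalized_gamma   Prentice form (location mu, scale sigma, shape q):
                    w = q**-2 * exp(q*z);  S = Q(q**-2, w) for q > 0,
                    P(q**-2, w) for q < 0, log-normal limit at q = 0
==================  =====================================================

``P``/``Q`` are the regularized lower/upper incomplete gamma functions.  In
the Prentice form the generalized gamma nests Weibull at ``q = 1``, the
log-normal at ``q = 0`` and the gamma family above at ``q = scale`` (with
gamma shape ``1/scale**2``), all at interior parameter values, which keeps
maximum-likelihood fits away from boundary pathologies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "DistributionFamily",
    "DistributionParams",
    "survival",
    "hazard",
    "density",
    "quantile",
    "quantile_from_survival",
    "apply_aft",
    "sample_time",
    "ImpossibleConditioningError",
]

# Treat |q| below this as the log-normal limit of the generalized gamma.
_GG_LOGNORMAL_EPS = 1e-8


class DistributionFamily(str, enum.Enum):
    """The six parametric time-to-event families."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"
    GAMMA = "gamma"
    GENERALIZED_GAMMA = "generalized_gamma"

    @property
    def n_params(self) -> int:
        """Number of free distributional parameters (family arity)."""
        return _ARITY[self]

    @property
    def has_scale(self) -> bool:
        return self not in (DistributionFamily.EXPONENTIAL, DistributionFamily.GAMMA)

    @property
    def has_shape(self) -> bool:
        return self in (DistributionFamily.GAMMA, DistributionFamily.GENERALIZED_GAMMA)


_ARITY = {
    DistributionFamily.EXPONENTIAL: 1,
    DistributionFamily.WEIBULL: 2,
    DistributionFamily.LOGNORMAL: 2,
    DistributionFamily.LOGLOGISTIC: 2,
    DistributionFamily.GAMMA: 2,
    DistributionFamily.GENERALIZED_GAMMA: 3,
}


class ImpossibleConditioningError(ValueError):
    """Raised when conditioning on survival past a time with S(t0) = 0."""


@dataclass(frozen=True)
class DistributionParams:
    """Parameters of one family in location/scale/shape AFT form.

    location is on the log-time (log-days) scale; scale and shape are
    positive where the family uses them (gamma has no free scale; the
    generalized-gamma shape ``q`` may be any real, with q = 0 the
    log-normal limit).
    """

    family: DistributionFamily
    location: float
    scale: float = 1.0
    shape: Optional[float] = None

    def __post_init__(self) -> None:
        fam = DistributionFamily(self.family)
        object.__setattr__(self, "family", fam)
        if not np.isfinite(self.location):
            raise ValueError("location must be finite")
        if self.scale <= 0 or not np.isfinite(self.scale):
            raise ValueError(f"scale must be positive, got {self.scale}")
        if fam.has_shape:
            if self.shape is None:
                raise ValueError(f"{fam.value} requires a shape parameter")
            if fam is DistributionFamily.GAMMA and self.shape <= 0:
                raise ValueError(f"gamma shape must be positive, got {self.shape}")
            if not np.isfinite(self.shape):
                raise ValueError("shape must be finite")
        elif self.shape is not None:
            raise ValueError(f"{fam.value} takes no shape parameter")
        if not fam.has_scale and self.scale != 1.0:
            raise ValueError(f"{fam.value} has no free scale; leave scale = 1")

    def shifted(self, delta: float) -> "DistributionParams":
        """Return a copy with the location shifted by ``delta`` (AFT shift)."""
        return replace(self, location=self.location + delta)


# ---------------------------------------------------------------------------
# vectorized log-survival / log-density kernels
# (array-friendly: t and loc broadcast; scale/shape scalar)
# ---------------------------------------------------------------------------


def _log_sf(family: DistributionFamily, t, loc, scale: float, shape) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family is DistributionFamily.EXPONENTIAL:
            return -t * np.exp(-loc)
        if family is DistributionFamily.WEIBULL:
            logw = (np.log(t) - loc) / scale
            return -np.exp(logw)
        if family is DistributionFamily.LOGNORMAL:
            z = (np.log(t) - loc) / scale
            return special.log_ndtr(-z)
        if family is DistributionFamily.LOGLOGISTIC:
            logw = (np.log(t) - loc) / scale
            return -np.logaddexp(0.0, logw)
        if family is DistributionFamily.GAMMA:
            a = shape
            x = a * t * np.exp(-loc)
            return np.log(special.gammaincc(a, x))
        if family is DistributionFamily.GENERALIZED_GAMMA:
            q = shape
            if abs(q) < _GG_LOGNORMAL_EPS:
                z = (np.log(t) - loc) / scale
                return special.log_ndtr(-z)
            a = q ** -2
            z = (np.log(t) - loc) / scale
            w = a * np.exp(q * z)
            if q > 0:
                return np.log(special.gammaincc(a, w))
            return np.log(special.gammainc(a, w))
    raise ValueError(f"unknown family {family}")


def _log_pdf(family: DistributionFamily, t, loc, scale: float, shape) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logt = np.log(t)
        if family is DistributionFamily.EXPONENTIAL:
            return -loc - t * np.exp(-loc)
        if family is DistributionFamily.WEIBULL:
            logw = (logt - loc) / scale
            return -math.log(scale) - logt + logw - np.exp(logw)
        if family is DistributionFamily.LOGNORMAL:
            z = (logt - loc) / scale
            return -math.log(scale) - logt - 0.5 * z * z - 0.5 * math.log(2 * math.pi)
        if family is DistributionFamily.LOGLOGISTIC:
            logw = (logt - loc) / scale
            return logw - math.log(scale) - logt - 2.0 * np.logaddexp(0.0, logw)
        if family is DistributionFamily.GAMMA:
            a = shape
            logx = math.log(a) + logt - loc
            x = np.exp(logx)
            return (
                math.log(a)
                - loc
                + (a - 1.0) * logx
                - x
                - special.gammaln(a)
            )
        if family is DistributionFamily.GENERALIZED_GAMMA:
            q = shape
            z = (logt - loc) / scale
            if abs(q) < _GG_LOGNORMAL_EPS:
                return (
                    -math.log(scale) - logt - 0.5 * z * z - 0.5 * math.log(2 * math.pi)
                )
            a = q ** -2
            return (
                math.log(abs(q))
                - math.log(scale)
                - logt
                + a * math.log(a)
                - special.gammaln(a)
                + a * (q * z - np.exp(q * z))
            )
    raise ValueError(f"unknown family {family}")


def _sf_inverse(family: DistributionFamily, s, loc, scale: float, shape) -> np.ndarray:
    """Solve S(t) = s for t, vectorized over s (each s in (0, 1])."""
    s = np.asarray(s, dtype=float)
    if family is DistributionFamily.EXPONENTIAL:
        return -np.log(s) * np.exp(loc)
    if family is DistributionFamily.WEIBULL:
        with np.errstate(divide="ignore"):
            return np.exp(loc + scale * np.log(-np.log(s)))
    if family is DistributionFamily.LOGNORMAL:
        return np.exp(loc + scale * special.ndtri(1.0 - s))
    if family is DistributionFamily.LOGLOGISTIC:
        with np.errstate(divide="ignore"):
            return np.exp(loc + scale * np.log(1.0 / s - 1.0))
    if family is DistributionFamily.GAMMA:
        a = shape
        x = special.gammainccinv(a, s)
        return x * np.exp(loc) / a
    if family is DistributionFamily.GENERALIZED_GAMMA:
        q = shape
        if abs(q) < _GG_LOGNORMAL_EPS:
            return np.exp(loc + scale * special.ndtri(1.0 - s))
        a = q ** -2
        w = special.gammainccinv(a, s) if q > 0 else special.gammaincinv(a, s)
        z = np.log(w / a) / q
        return np.exp(loc + scale * z)
    raise ValueError(f"unknown family {family}")


# ---------------------------------------------------------------------------
# public API on DistributionParams
# ---------------------------------------------------------------------------


def survival(params: DistributionParams, t):
    """Survival function S(t); t in days, t >= 0. S(0) = 1 for every family."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.ones_like(t_arr, dtype=float)
    pos = t_arr > 0
    if np.any(pos):
        out[pos] = np.exp(
            _log_sf(params.family, t_arr[pos], params.location, params.scale, params.shape)
        )
    return out if np.ndim(t) else float(out)


def density(params: DistributionParams, t):
    """Event-time density f(t), t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be positive")
    out = np.exp(
        _log_pdf(params.family, t_arr, params.location, params.scale, params.shape)
    )
    return out if np.ndim(t) else float(out)


def hazard(params: DistributionParams, t):
    """Instantaneous hazard h(t) = f(t) / S(t) per day, t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be positive")
    lp = _log_pdf(params.family, t_arr, params.location, params.scale, params.shape)
    ls = _log_sf(params.family, t_arr, params.location, params.scale, params.shape)
    out = np.exp(lp - ls)
    return out if np.ndim(t) else float(out)


def quantile_from_survival(params: DistributionParams, s):
    """Inverse survival: smallest t with S(t) = s, for s in (0, 1]."""
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr <= 0) | (s_arr > 1)):
        raise ValueError("survival probability must lie in (0, 1]")
    out = np.where(
        s_arr == 1.0,
        0.0,
        _sf_inverse(params.family, np.clip(s_arr, 1e-300, 1.0), params.location, params.scale, params.shape),
    )
    return out if np.ndim(s) else float(out)


def quantile(params: DistributionParams, p):
    """p-th quantile of the event time, p in [0, 1); quantile(0) = 0."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr >= 1)):
        raise ValueError("p must lie in [0, 1)")
    out = quantile_from_survival(params, 1.0 - p_arr)
    return out if np.ndim(p) else float(out)


def apply_aft(
    base: DistributionParams, x: np.ndarray, betas: np.ndarray
) -> DistributionParams:
    """Shift the location by the linear predictor x . beta.

    Under the AFT convention every quantile is multiplied by exp(x . beta):
    positive linear predictors lengthen event times (protective), negative
    ones shorten them (harmful).
    """
    x = np.asarray(x, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if x.shape != betas.shape:
        raise ValueError(
            f"covariate vector (len {x.shape}) and coefficients (len {betas.shape}) "
            "do not align"
        )
    return base.shifted(float(x @ betas))


def sample_time(
    params: DistributionParams,
    condition_exceeds: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw from T | T > condition_exceeds by inverting the survival function.

    Exact inverse-CDF conditioning: with U ~ Uniform(0, 1], the draw is
    S^{-1}(U * S(t0)), which always exceeds t0.  Deterministic given the
    generator state.
    """
    if condition_exceeds < 0:
        raise ValueError("condition_exceeds must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    s0 = survival(params, condition_exceeds) if condition_exceeds > 0 else 1.0
    if s0 <= 0.0:
        raise ImpossibleConditioningError(
            f"survival at t0={condition_exceeds} is zero; cannot condition"
        )
    u = 1.0 - rng.random()  # in (0, 1]
    target = u * s0
    t = quantile_from_survival(params, target)
    return float(max(t, np.nextafter(condition_exceeds, np.inf)))
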