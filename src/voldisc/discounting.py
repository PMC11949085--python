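"""Valuation models: hyperbolic, volatility, mean-variance, concave utility.

The core model values a delayed reward of expected magnitude X at

    x = X * 1/(1 + K t^s) * 1/(1 + m (eta^2 + sigma^2 t^s)) + c

combining a baseline hyperbolic discount (rate K, time exponent s) with
a volatility discount: the agent devalues reward in proportion to its
magnitude variance, weighted by a risk-aversion parameter m = 1/theta^2
where theta^2 is the agent's irreducible internal uncertainty.  With no
time-independent risk (eta = 0) the volatility factor is itself
hyperbolic in delay with rate K = m * sigma^2, so volatility produces
hyperbolic impatience.  The bias c applies to delayed/risky options
only.  Two alternative risk models are provided for comparison: an
additive mean-variance value and a concave (power) utility certainty
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

__all__ = [
    "DiscountParams",
    "ConditionSpec",
    "RiskAltParams",
    "hyperbolic_factor",
    "volatility_factor",
    "indifference_amount",
    "risk_certainty_equivalent",
    "mean_variance_value",
    "power_utility_certainty_equivalent",
]


@dataclass(frozen=True)
class DiscountParams:
    """Free parameters of the combined discount model.

    K : baseline discount rate, week^-s, >= 0
    m : volatility/risk-aversion weight, currency^-2, >= 0 (m = 1/theta^2)
    s : subjective time exponent, > 0
    c : additive bias in currency, applied to delayed/risky options only
    """

    K: float = 0.0
    m: float = 0.0
    s: float = 1.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not np.isfinite(self.c):
            raise ValueError("c must be finite")


@dataclass(frozen=True)
class ConditionSpec:
    """Objective uncertainty of one task condition.

    sigma2 : volatility variance, currency^2 per week
    eta2   : time-independent (emission) variance, currency^2
    """

    sigma2: float
    eta2: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.eta2 < 0:
            raise ValueError("sigma2 and eta2 must be >= 0")


@dataclass(frozen=True)
class RiskAltParams:
    """Parameters of the alternative risk models.

    lam : mean-variance penalty weight, currency^-1
    rho : power-utility curvature exponent, > 0 (rho < 1 is risk averse)
    """

    lam: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ValueError("lam must be finite")
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")


def hyperbolic_factor(t, K: float, s: float = 1.0):
    """Baseline hyperbolic discount fraction 1 / (1 + K * t**s).

    Vectorized over ``t``; equals 1 at t = 0 and decreases strictly in
    delay when K > 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    out = 1.0 / (1.0 + K * t**s)
    return float(out) if out.ndim == 0 else out


def volatility_factor(t, m: float, sigma2: float, eta2: float, s: float = 1.0):
    """Uncertainty discount fraction 1 / (1 + m * (eta2 + sigma2 * t**s)).

    At t = 0 this is the pure risk factor 1/(1 + m * eta2); with
    eta2 = 0 it coincides with a hyperbolic factor of rate K = m*sigma2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    if m < 0 or sigma2 < 0 or eta2 < 0:
        raise ValueError("m, sigma2 and eta2 must be >= 0")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    out = 1.0 / (1.0 + m * (eta2 + sigma2 * t**s))
    return float(out) if out.ndim == 0 else out


def indifference_amount(
    X, t, params: DiscountParams, cond: ConditionSpec
):
    """Immediate amount x at indifference with a delayed/risky reward X.

    x = X / (1 + K t^s) / (1 + m (eta2 + sigma2 t^s)) + c.  The bias c
    is added only when the option is actually delayed or risky (t > 0
    or the condition carries positive variance); an immediate certain
    option is returned undiscounted.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("expected magnitude X must be > 0")
    t = np.asarray(t, dtype=float)
    risky = (t > 0) | (cond.sigma2 > 0) | (cond.eta2 > 0)
    value = (
        X
        * hyperbolic_factor(t, params.K, params.s)
        * volatility_factor(t, params.m, cond.sigma2, cond.eta2, params.s)
        + np.where(risky, params.c, 0.0)
    )
    return float(value) if value.ndim == 0 else value


def risk_certainty_equivalent(X, eta2, m: float, c: float = 0.0):
    """Certainty equivalent of a same-day lottery with mean X, variance eta2.

    The delay-0 special case of the combined model: X/(1 + m*eta2) + c,
    with c applied whenever the option is risky (eta2 > 0).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("lottery mean must be > 0")
    eta2 = np.asarray(eta2, dtype=float)
    if np.any(eta2 < 0):
        raise ValueError("lottery variance must be >= 0")
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    out = X / (1.0 + m * eta2) + np.where(eta2 > 0, c, 0.0)
    return float(out) if out.ndim == 0 else out


def mean_variance_value(mean, variance, lam: float):
    """Additive mean-variance value: mean - lam * variance."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("variance must be >= 0")
    out = np.asarray(mean, dtype=float) - lam * variance
    return float(out) if out.ndim == 0 else out


# Gauss-Hermite nodes for the power-utility expectation; 24 nodes give
# CE accuracy far below 0.01 for the task's price distributions.
_GH_NODES, _GH_WEIGHTS = hermegauss(24)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()
_GH_LOGW = np.log(_GH_WEIGHTS)


def power_utility_certainty_equivalent(mean, variance, rho: float):
    """Certainty equivalent under power utility u(r) = r**rho.

    The reward is Gaussian with the given mean and variance, truncated
    at zero (magnitudes are positive); E[u] is computed by
    Gauss-Hermite quadrature over the truncated density and inverted,
    CE = E[u]^(1/rho).  Equals the mean when variance = 0 or rho = 1.
    """
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0")
    if np.any(variance < 0):
        raise ValueError("variance must be >= 0")
    scalar = mean.ndim == 0 and variance.ndim == 0
    mean, variance = np.broadcast_arrays(np.atleast_1d(mean), np.atleast_1d(variance))
    sd = np.sqrt(variance)
    r = mean[..., None] + sd[..., None] * _GH_NODES  # quadrature abscissae
    pos = r > 0
    # log-space accumulation keeps large rho (or magnitudes) finite
    log_u = np.where(pos, rho * np.log(np.where(pos, r, 1.0)), -np.inf)
    x = log_u + _GH_LOGW
    mx = np.max(x, axis=-1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    log_eu = np.squeeze(mx, -1) + np.log(np.sum(np.exp(x - mx), axis=-1))
    mass = np.where(sd > 0, ndtr(mean / np.where(sd > 0, sd, 1.0)), 1.0)
    log_eu = log_eu - np.log(mass)  # renormalise for the truncation at 0
    ce = np.where(sd > 0, np.exp(log_eu / rho), mean)
    if not np.all(np.isfinite(ce)):
        raise ArithmeticError(
            f"power-utility quadrature produced non-finite CE "
            f"(rho={rho}, mean range [{mean.min()}, {mean.max()}])"
        )
    return float(ce[0]) if scalar else ce
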