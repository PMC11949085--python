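"""Learning-rate estimation and state-space oracles.

Agents track the drifting market price with a Rescorla-Wagner (delta)
rule, V <- V + alpha * (r - V).  This module fits the learning rate
alpha to a subject's one-week-ahead price predictions, computes the
normatively optimal alpha for a given price process (the rate that
minimizes one-step squared prediction error), and provides two
state-space references for the same process: the steady-state Kalman
gain (the asymptotic optimal alpha for an unbounded walk) and
maximum-likelihood estimation of the walk's volatility and emission
noise via the exact Kalman-filter likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from voldisc.generative import RandomWalkSpec, simulate_price_series

__all__ = [
    "RWParams",
    "LearningFit",
    "rw_filter",
    "fit_rw_alpha",
    "optimal_alpha",
    "steady_state_kalman_gain",
    "kalman_negloglik",
    "fit_state_space_mle",
]


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters: learning rate alpha in [0, 1] and
    initial value estimate v0 (currency)."""

    alpha: float
    v0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class LearningFit:
    """Result of a learning-rate fit."""

    params: RWParams
    sse: float
    n_obs: int
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


def rw_filter(prices, params: RWParams) -> np.ndarray:
    """One-step-ahead Rescorla-Wagner predictions for a price sequence.

    The prediction for trial t is formed before r_t is seen:
    V_1 = v0 and V_{t+1} = V_t + alpha * (r_t - V_t).
    """
    prices = np.asarray(prices, dtype=float)
    if prices.size == 0:
        raise ValueError("price sequence must be non-empty")
    alpha = params.alpha
    preds = np.empty_like(prices)
    v = params.v0
    for t, r in enumerate(prices):
        preds[t] = v
        v = v + alpha * (r - v)
    return preds


def _rw_sse(alpha: float, prices: np.ndarray, targets: np.ndarray, v0: float) -> float:
    v = v0
    sse = 0.0
    for r, y in zip(prices, targets):
        d = y - v
        sse += d * d
        v = v + alpha * (r - v)
    return sse


def _fit_alpha_1d(prices: np.ndarray, targets: np.ndarray, v0: float) -> tuple[float, float]:
    """Bounded alpha search: golden-section refinement from multi-starts."""
    best = (math.inf, 0.0)
    for lo, hi in [(0.0, 0.25), (0.2, 0.45), (0.4, 0.65), (0.6, 0.85), (0.8, 1.0)]:
        res = minimize_scalar(
            _rw_sse,
            bounds=(lo, hi),
            args=(prices, targets, v0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun < best[0]:
            best = (res.fun, float(res.x))
    # endpoints are not interior optima of the bounded search
    for a in (0.0, 1.0):
        sse = _rw_sse(a, prices, targets, v0)
        if sse < best[0] - 1e-12:
            best = (sse, a)
    return best[1], best[0]


def fit_rw_alpha(prices, subject_predictions, v0: str | float = "first_price") -> LearningFit:
    """Fit the learning rate to a subject's one-step price predictions.

    Minimizes squared error between the RW filter's one-step-ahead
    predictions and the subject's stated predictions.  ``v0`` is the
    filter's initial value: ``"first_price"`` (default) anchors it at
    the first observed price; a float fixes it explicitly.
    """
    prices = np.asarray(prices, dtype=float)
    preds = np.asarray(subject_predictions, dtype=float)
    if prices.shape != preds.shape:
        raise ValueError("prices and predictions must be aligned")
    if preds.size < 3:
        raise ValueError("need at least 3 prediction trials to fit alpha")
    v0_val = float(prices[0]) if v0 == "first_price" else float(v0)
    alpha, sse = _fit_alpha_1d(prices, preds, v0_val)
    return LearningFit(
        params=RWParams(alpha=alpha, v0=v0_val), sse=sse, n_obs=int(preds.size)
    )


def _optimal_alpha_series(observed: np.ndarray, v0: float) -> float:
    """Alpha minimizing one-step squared prediction error of a series."""
    # targets are the observed prices themselves (self-prediction)
    alpha, _ = _fit_alpha_1d(observed[1:], observed[1:], v0)
    return alpha


def optimal_alpha(
    spec: RandomWalkSpec, n_series: int, seed: int
) -> tuple[float, float, bool]:
    """Mean optimal RW learning rate for a price process.

    For each of ``n_series`` simulated series, finds the alpha that
    minimizes mean squared one-step-ahead prediction error of the
    observed prices (filter initialized at the first observed price),
    and returns ``(mean_alpha, standard_error, degenerate)`` across
    series.  A process with sigma = eta = 0 is degenerate: every alpha
    predicts the constant price exactly.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    degenerate = spec.sigma == 0 and spec.eta == 0
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_series)
    alphas = np.empty(n_series)
    for i, s in enumerate(seeds):
        series = simulate_price_series(spec, int(s))
        obs = series.observed
        alphas[i] = _optimal_alpha_series(obs, v0=float(obs[0]))
    se = float(alphas.std(ddof=1) / math.sqrt(n_series)) if n_series > 1 else 0.0
    return float(alphas.mean()), se, degenerate


def steady_state_kalman_gain(sigma2: float, eta2: float) -> float:
    """Asymptotic Kalman gain for a random walk observed in noise.

    Fixed point of P <- (P + sigma2) * eta2 / (P + sigma2 + eta2) with
    gain (P + sigma2) / (P + sigma2 + eta2); the normative benchmark
    for the RW learning rate on an unbounded walk.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if eta2 < 0:
        raise ValueError("eta2 must be >= 0")
    if eta2 == 0:
        return 1.0
    p = 0.0
    for _ in range(10_000):
        p_new = (p + sigma2) * eta2 / (p + sigma2 + eta2)
        if abs(p_new - p) < 1e-12:
            p = p_new
            break
        p = p_new
    return (p + sigma2) / (p + sigma2 + eta2)


def kalman_negloglik(
    observed, sigma: float, eta: float, r0: float, prior_var: float = 0.0
) -> float:
    """Exact negative log likelihood of an unbounded walk + noise model.

    Scalar Kalman filter with known initial latent price ``r0`` (prior
    variance ``prior_var``); each observation contributes a Gaussian
    innovation term.  ``sigma`` is the walk SD per week, ``eta`` the
    emission SD.
    """
    observed = np.asarray(observed, dtype=float)
    if sigma < 0 or eta < 0:
        raise ValueError("sigma and eta must be >= 0")
    sigma2, eta2 = sigma * sigma, eta * eta
    mu, p = float(r0), float(prior_var)
    nll = 0.0
    log2pi = math.log(2.0 * math.pi)
    for y in observed:
        p_pred = p + sigma2
        s_innov = p_pred + eta2
        if s_innov <= 0:
            return math.inf
        d = y - mu
        nll += 0.5 * (log2pi + math.log(s_innov) + d * d / s_innov)
        gain = p_pred / s_innov
        mu = mu + gain * d
        p = p_pred * (1.0 - gain)
    return nll


def fit_state_space_mle(
    observed,
    r0: float,
    eta: float | None = None,
    sigma_bounds: tuple[float, float] = (1e-4, 20.0),
    eta_bounds: tuple[float, float] = (1e-4, 20.0),
) -> dict:
    """Maximum-likelihood volatility (and optionally emission) SD.

    With ``eta`` given, maximizes the Kalman likelihood over the
    volatility SD alone; with ``eta=None`` both SDs are estimated
    jointly (Nelder-Mead in log space, multi-start).  Returns a dict
    with ``sigma_hat``, ``eta_hat`` and the optimum ``negloglik``.
    """
    observed = np.asarray(observed, dtype=float)
    if eta is not None:
        res = minimize_scalar(
            lambda s: kalman_negloglik(observed, s, eta, r0),
            bounds=sigma_bounds,
            method="bounded",
            options={"xatol": 1e-6},
        )
        return {
            "sigma_hat": float(res.x),
            "eta_hat": float(eta),
            "negloglik": float(res.fun),
        }

    def nll_log(z):
        return kalman_negloglik(observed, math.exp(z[0]), math.exp(z[1]), r0)

    best = None
    for s0, e0 in [(1.0, 1.0), (3.0, 3.0), (0.3, 5.0)]:
        res = minimize(
            nll_log,
            x0=[math.log(s0), math.log(e0)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    sig = min(max(math.exp(best.x[0]), sigma_bounds[0]), sigma_bounds[1])
    et = min(max(math.exp(best.x[1]), eta_bounds[0]), eta_bounds[1])
    return {"sigma_hat": sig, "eta_hat": et, "negloglik": float(best.fun)}
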