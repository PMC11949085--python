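"""Subjective future uncertainty (SFU) from confidence-interval reports.

Participants report 90% confidence intervals for the price at several
future delays.  Under the random-walk generative model the interval
half-width at delay t is z * sqrt(sigma^2 * t + theta0^2), with z the
two-sided Gaussian quantile for the stated coverage.  Regressing
squared half-widths on delay therefore recovers the subject's implied
volatility sigma_hat^2 (the SFU) as the slope and a time-independent
uncertainty theta0_hat^2 as the intercept; the regression is exactly
invertible for noise-free reports.  Best-guess growth over delay is
summarised by a log growth curve a + b*log(1 + t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["IntervalReport", "SFUFit", "interval_halfwidth", "fit_sfu", "fit_growth_curve"]


@dataclass(frozen=True)
class IntervalReport:
    """One reported 90% interval at delay ``t`` weeks."""

    t: float
    lower: float
    upper: float
    best_guess: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"delay must be >= 0, got {self.t}")
        if not self.lower <= self.best_guess <= self.upper:
            raise ValueError(
                f"require lower <= best_guess <= upper, got "
                f"({self.lower}, {self.best_guess}, {self.upper})"
            )

    @property
    def halfwidth(self) -> float:
        # asymmetric reports are symmetrized
        return (self.upper - self.lower) / 2.0


@dataclass(frozen=True)
class SFUFit:
    """Fitted subjective uncertainty: SFU is ``sigma_hat ** 2``."""

    sigma_hat: float
    theta0_hat: float
    rmse: float

    def __post_init__(self) -> None:
        if self.sigma_hat < 0 or self.theta0_hat < 0:
            raise ValueError("sigma_hat and theta0_hat must be >= 0")

    @property
    def sfu(self) -> float:
        return self.sigma_hat**2


def _z(coverage: float) -> float:
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    return float(norm.ppf(0.5 + coverage / 2.0))


def interval_halfwidth(
    t, sigma2: float, theta0_sq: float, coverage: float = 0.90
):
    """Half-width of the central ``coverage`` interval at delay ``t``.

    z(coverage) * sqrt(sigma2 * t + theta0_sq); z = 1.6449 for 90%.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    if sigma2 < 0 or theta0_sq < 0:
        raise ValueError("variances must be >= 0")
    out = _z(coverage) * np.sqrt(sigma2 * t + theta0_sq)
    return float(out) if out.ndim == 0 else out


def fit_sfu(reports: Sequence[IntervalReport], coverage: float = 0.90) -> SFUFit:
    """Fit the random-walk interval model to a subject's reports.

    Least-squares regression of squared half-widths (divided by z^2)
    on delay; the slope is sigma_hat^2 (clipped at 0), the intercept
    theta0_hat^2 (clipped at 0).  Raises if all delays coincide
    (slope unidentifiable) or no interval was adjusted away from zero
    width (an inattentive subject, excluded upstream).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 interval reports")
    t = np.array([r.t for r in reports], dtype=float)
    hw = np.array([r.halfwidth for r in reports], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all delays identical: volatility unidentifiable")
    if np.all(hw == 0):
        raise ValueError("all intervals have zero width (unadjusted reports)")
    z = _z(coverage)
    y = (hw / z) ** 2
    slope, intercept = np.polyfit(t, y, 1)
    sigma2_hat = max(float(slope), 0.0)
    theta0_sq_hat = max(float(intercept), 0.0)
    fitted = z * np.sqrt(sigma2_hat * t + theta0_sq_hat)
    rmse = float(np.sqrt(np.mean((fitted - hw) ** 2)))
    return SFUFit(
        sigma_hat=float(np.sqrt(sigma2_hat)),
        theta0_hat=float(np.sqrt(theta0_sq_hat)),
        rmse=rmse,
    )


def fit_growth_curve(best_guesses: Sequence[tuple[float, float]]) -> dict:
    """Fit value = a + b * log(1 + t) to (delay, best guess) pairs.

    Also reports the ordinary linear slope in t, used to check that
    predicted prices are flat over delay (a driftless walk).
    """
    if len(best_guesses) < 2:
        raise ValueError("need at least 2 (t, value) pairs")
    t = np.array([p[0] for p in best_guesses], dtype=float)
    v = np.array([p[1] for p in best_guesses], dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    if np.ptp(t) == 0:
        raise ValueError("all delays identical: growth slope unidentifiable")
    b, a = np.polyfit(np.log1p(t), v, 1)
    lin_slope = float(np.polyfit(t, v, 1)[0])
    return {"a": float(a), "b": float(b), "linear_slope": lin_slope}
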