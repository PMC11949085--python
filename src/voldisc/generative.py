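"""Generative reward environment: bounded Gaussian random-walk prices.

A latent market price R_t evolves as a driftless Gaussian random walk
with volatility SD ``sigma`` (currency per sqrt(week)); the price shown
to the agent on each trial is the latent price plus i.i.d. Gaussian
emission noise with SD ``eta``.  Both the latent path and the observed
prices are clipped to the task's price bounds at every step.  Under the
unbounded process the observed price at delay t has mean R_0 and
variance ``sigma^2 * t + eta^2``; with a subjective time exponent s the
time-dependent term generalises to ``sigma^2 * t^s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RandomWalkSpec",
    "PriceSeries",
    "simulate_price_series",
    "reward_variance",
    "load_design_config",
    "packaged_config_path",
]


@dataclass(frozen=True)
class RandomWalkSpec:
    """Parameters of the bounded random-walk price process.

    Parameters
    ----------
    sigma
        Volatility SD of the latent walk, in currency / sqrt(week).
    eta
        Emission-noise SD on observed prices, in currency.
    r0
        Initial latent market price (known to the agent).
    lower, upper
        Price bounds; both the latent path and the observations are
        clipped to [lower, upper].  Use ``bounded=False`` to disable.
    n_trials
        Number of weekly price observations to generate.
    drift
        Mean drift per week; zero in every task configuration.
    bounded
        If False the walk is left unclipped (analytic moments then hold
        exactly; used by recovery harnesses and state-space fitting).
    """

    sigma: float
    eta: float
    r0: float
    lower: float = 0.0
    upper: float = 50.0
    n_trials: int = 240
    drift: float = 0.0
    bounded: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.bounded:
            if not self.lower < self.upper:
                raise ValueError(
                    f"require lower < upper, got [{self.lower}, {self.upper}]"
                )
            if not self.lower < self.r0 < self.upper:
                raise ValueError(
                    f"r0={self.r0} must lie strictly inside "
                    f"[{self.lower}, {self.upper}]"
                )


@dataclass(frozen=True)
class PriceSeries:
    """One simulated price sequence.

    ``latent[i]`` is the latent market price after i+1 weekly
    innovations from the initial price ``spec.r0``; ``observed[i]`` is
    the corresponding noisy price shown to the agent.
    """

    latent: np.ndarray
    observed: np.ndarray
    spec: RandomWalkSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.latent) != len(self.observed):
            raise ValueError("latent and observed must have equal length")

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a (trial, latent, observed) table, prices in £0.01."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.latent) + 1),
                "latent": np.round(self.latent, 2),
                "observed": np.round(self.observed, 2),
            }
        )


def simulate_price_series(spec: RandomWalkSpec, seed: int) -> PriceSeries:
    """Simulate one bounded random-walk price series.

    The same (spec, seed) pair always yields a bit-identical series.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_trials
    latent = np.empty(n)
    r = spec.r0
    steps = rng.normal(spec.drift, spec.sigma, size=n) if spec.sigma > 0 or spec.drift != 0 else np.zeros(n)
    for t in range(n):
        r = r + steps[t]
        if spec.bounded:
            r = min(max(r, spec.lower), spec.upper)
        latent[t] = r
    if spec.eta > 0:
        observed = latent + rng.normal(0.0, spec.eta, size=n)
    else:
        observed = latent.copy()
    if spec.bounded:
        observed = np.clip(observed, spec.lower, spec.upper)
    return PriceSeries(latent=latent, observed=observed, spec=spec, seed=seed)


def reward_variance(
    t: float, sigma2: float, vartheta2: float, s: float = 1.0
) -> float:
    """Variance of the reward observed at delay ``t`` weeks.

    Returns ``sigma2 * t**s + vartheta2``: random-walk increments
    accumulate linearly in (subjective) time while the emission
    component is time-independent.
    """
    if t < 0:
        raise ValueError(f"delay must be >= 0, got {t}")
    if sigma2 < 0 or vartheta2 < 0:
        raise ValueError("variances must be >= 0")
    if s <= 0:
        raise ValueError(f"time exponent must be > 0, got {s}")
    return sigma2 * t**s + vartheta2


_CONFIG_DIR = Path(__file__).parent / "configs"


def packaged_config_path(name: str) -> Path:
    """Path of a packaged experiment design config (e.g. ``"exp2"``)."""
    path = _CONFIG_DIR / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in _CONFIG_DIR.glob("*.yaml"))
        raise FileNotFoundError(f"no config {name!r}; available: {available}")
    return path


def load_design_config(source: Union[str, Path]) -> dict:
    """Load an experiment design config from YAML.

    ``source`` may be a packaged config name ("exp1", "exp2", "exp3")
    or a filesystem path.  Returns the raw dict; condition entries can
    be turned into :class:`RandomWalkSpec` via :func:`walk_spec_from_config`.
    """
    path = Path(source)
    if not path.exists():
        path = packaged_config_path(str(source))
    with open(path) as fh:
        return yaml.safe_load(fh)


def walk_spec_from_config(cfg: dict, condition: str, **overrides) -> RandomWalkSpec:
    """Build the RandomWalkSpec for one named condition of a design config."""
    conditions = {c["label"]: c for c in cfg["conditions"]}
    if condition not in conditions:
        raise KeyError(f"unknown condition {condition!r}; have {sorted(conditions)}")
    c = conditions[condition]
    kwargs = dict(
        sigma=float(c["sigma"]),
        eta=float(c["eta"]),
        r0=float(cfg["r0"]),
        lower=float(cfg["lower"]),
        upper=float(cfg["upper"]),
        n_trials=int(cfg.get("n_learning_trials", 240)),
    )
    kwargs.update(overrides)
    return RandomWalkSpec(**kwargs)
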