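"""Synthetic cohorts reproducing the marketplace task designs.

Simulated agents live in the random-walk price environment, learn
prices with a Rescorla-Wagner rule, report interval forecasts whose
width grows with the square root of accumulated variance, and value
delayed sales with the combined hyperbolic + volatility discount model.
The module generates trial-level data for whole cohorts under any of
the three packaged designs (direct indifference reports, binary choice
sets, or adaptive bisection staircases), and provides the end-to-end
analysis harness: hierarchical fits, model comparison, per-condition
discount-rate regressions and cross-parameter correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import pearsonr, spearmanr

from voldisc.discounting import ConditionSpec, DiscountParams, indifference_amount
from voldisc.generative import (
    RandomWalkSpec,
    load_design_config,
    simulate_price_series,
    walk_spec_from_config,
)
from voldisc.inference import (
    ModelSpec,
    SubjectData,
    compare_models,
    fit_group_em,
    subject_reliability,
)
from voldisc.learning import RWParams, rw_filter
from voldisc.uncertainty import interval_halfwidth

__all__ = [
    "ExperimentDesign",
    "PopulationSpec",
    "SubjectRecord",
    "simulate_subject",
    "adaptive_indifference",
    "simulate_cohort",
    "weighted_condition_regression",
    "run_experiment_pipeline",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Task design: conditions, delays and elicitation mechanics."""

    name: str
    conditions: tuple[ConditionSpec, ...]
    walk_specs: tuple[RandomWalkSpec, ...]
    delays: tuple[float, ...]
    elicitation: str = "direct_indifference"  # | binary_set | adaptive_staircase
    n_reports_per_cell: int = 3
    n_immediate_amounts: int = 7   # binary_set: grid size per delay
    n_staircase_steps: int = 6
    n_prediction_trials: int = 70

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.delays):
            raise ValueError("delays must be non-negative")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if len(self.conditions) != len(self.walk_specs):
            raise ValueError("one walk spec per condition required")
        if self.elicitation not in {
            "direct_indifference",
            "binary_set",
            "adaptive_staircase",
        }:
            raise ValueError(f"unknown elicitation {self.elicitation!r}")

    @classmethod
    def from_config(cls, source, **overrides) -> "ExperimentDesign":
        cfg = load_design_config(source)
        conds, walks = [], []
        for c in cfg["conditions"]:
            walks.append(walk_spec_from_config(cfg, c["label"]))
            conds.append(
                ConditionSpec(
                    sigma2=float(c["sigma"]) ** 2,
                    eta2=float(c["eta"]) ** 2,
                    label=c["label"],
                )
            )
        kwargs = dict(
            name=cfg["name"],
            conditions=tuple(conds),
            walk_specs=tuple(walks),
            delays=tuple(float(d) for d in cfg["delays_weeks"]),
            elicitation=cfg.get("elicitation", "direct_indifference"),
            n_prediction_trials=int(cfg.get("n_prediction_trials", 70)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions of true subject parameters.

    log K and log m are jointly Gaussian with correlation ``corr_km``;
    s is log-normal, c Gaussian, the learning rate Beta.  Report noise
    is the SD of Gaussian noise added to stated indifference amounts;
    interval-width noise perturbs reported half-widths.  ``sfu_scale``
    multiplies the true volatility SD to yield the agent's subjective
    volatility (1 = veridical).
    """

    mu_log_k: float = -3.0
    sd_log_k: float = 1.0
    mu_log_m: float = -7.44
    sd_log_m: float = 1.0
    corr_km: float = 0.0
    mu_log_s: float = 0.0
    sd_log_s: float = 0.05
    mu_c: float = 0.0
    sd_c: float = 0.25
    alpha_a: float = 6.0
    alpha_b: float = 3.0
    report_noise_sd: float = 1.0
    interval_noise_sd: float = 0.5
    prediction_noise_sd: float = 0.5
    beta_choice: float = 2.0
    sfu_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sd_log_k", "sd_log_m", "sd_log_s", "sd_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.corr_km <= 1.0:
            raise ValueError("corr_km must be in [-1, 1]")

    def draw(self, rng: np.random.Generator) -> dict:
        cov = self.corr_km * self.sd_log_k * self.sd_log_m
        log_k, log_m = rng.multivariate_normal(
            [self.mu_log_k, self.mu_log_m],
            [[self.sd_log_k**2, cov], [cov, self.sd_log_m**2]],
        )
        return {
            "K": float(np.exp(log_k)),
            "m": float(np.exp(log_m)),
            "s": float(np.exp(rng.normal(self.mu_log_s, self.sd_log_s))),
            "c": float(rng.normal(self.mu_c, self.sd_c)),
            "alpha": float(rng.beta(self.alpha_a, self.alpha_b)),
            "beta_choice": self.beta_choice,
            "report_noise_sd": self.report_noise_sd,
            "interval_noise_sd": self.interval_noise_sd,
            "prediction_noise_sd": self.prediction_noise_sd,
            "sfu_scale": self.sfu_scale,
        }


@dataclass
class SubjectRecord:
    """True parameters plus the data generated from them."""

    subject_id: str
    true_params: dict
    data: SubjectData
    predictions: pd.DataFrame  # learning phase (condition, trial, observed, predicted)
    intervals: pd.DataFrame    # (condition, t, lower, upper, best_guess)
    seed: int


def _agent_value(X, t, params: DiscountParams, cond: ConditionSpec) -> float:
    return float(indifference_amount(X, t, params, cond))


def adaptive_indifference(
    value: float,
    X: float,
    beta: float,
    rng: np.random.Generator,
    n_steps: int = 6,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Bisection staircase estimate of an agent's indifference amount.

    The immediate offer starts at the midpoint of ``bounds`` (default
    [0, X]); the agent accepts the immediate offer with probability
    expit(beta * (offer - value)), and each response halves the
    interval toward the indifference point.  With a deterministic agent
    (beta = inf) the estimate is within range / 2**n_steps of ``value``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    lo, hi = bounds if bounds is not None else (0.0, X)
    for _ in range(n_steps):
        offer = 0.5 * (lo + hi)
        p_immediate = 1.0 if np.isinf(beta) and offer > value else (
            0.0 if np.isinf(beta) else expit(beta * (offer - value))
        )
        if rng.random() < p_immediate:
            hi = offer  # immediate accepted: indifference is below offer
        else:
            lo = offer
    return 0.5 * (lo + hi)


def _immediate_grid(X: float, n: int) -> np.ndarray:
    # geometric grid in (0, X], bracketing a plausible range of rates
    return X * np.geomspace(0.15, 1.0, n)


def simulate_subject(
    true_params: dict,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "s0",
) -> SubjectRecord:
    """Generate one agent's trials across all task phases.

    The agent learns each condition's prices with its Rescorla-Wagner
    rate, reports interval forecasts whose half-width follows
    z * sqrt(sfu_scale^2 * sigma^2 * t + eta^2) plus width noise, and
    values delayed sales by the combined discount model; indifference
    reports add Gaussian report noise, binary and staircase choices use
    a logistic rule with the agent's inverse temperature.
    """
    rng = np.random.default_rng(seed)
    dparams = DiscountParams(
        K=true_params["K"],
        m=true_params["m"],
        s=true_params.get("s", 1.0),
        c=true_params.get("c", 0.0),
    )
    beta = true_params.get("beta_choice", 2.0)
    pred_rows, interval_rows, indiff_rows, choice_rows = [], [], [], []
    for cond, walk in zip(design.conditions, design.walk_specs):
        series = simulate_price_series(walk, int(rng.integers(2**31 - 1)))
        obs = series.observed
        n_pred = min(design.n_prediction_trials, len(obs))
        preds = rw_filter(obs[:n_pred], RWParams(true_params["alpha"], float(obs[0])))
        noisy_preds = preds + rng.normal(
            0.0, true_params.get("prediction_noise_sd", 0.0), size=n_pred
        )
        for tr in range(n_pred):
            pred_rows.append(
                {
                    "condition": cond.label,
                    "trial": tr + 1,
                    "observed_price": obs[tr],
                    "predicted_price": noisy_preds[tr],
                }
            )
        X = walk.r0  # driftless walk: veridical expectation is the start price
        sfu_sigma2 = (true_params.get("sfu_scale", 1.0) ** 2) * cond.sigma2
        for t in design.delays:
            hw = interval_halfwidth(t, sfu_sigma2, cond.eta2)
            hw = max(hw + rng.normal(0.0, true_params.get("interval_noise_sd", 0.0)), 0.0)
            interval_rows.append(
                {
                    "condition": cond.label,
                    "t": t,
                    "lower": X - hw,
                    "upper": X + hw,
                    "best_guess": X,
                }
            )
            value = _agent_value(X, t, dparams, cond)
            if design.elicitation == "direct_indifference":
                for _ in range(design.n_reports_per_cell):
                    indiff_rows.append(
                        {
                            "condition": cond.label,
                            "X": X,
                            "t": t,
                            "sigma2": cond.sigma2,
                            "eta2": cond.eta2,
                            "x_report": value
                            + rng.normal(0.0, true_params["report_noise_sd"]),
                        }
                    )
            elif design.elicitation == "binary_set":
                for x_imm in _immediate_grid(X, design.n_immediate_amounts):
                    p_delayed = expit(beta * (value - x_imm))
                    choice_rows.append(
                        {
                            "condition": cond.label,
                            "x_immediate": float(x_imm),
                            "X": X,
                            "t": t,
                            "sigma2": cond.sigma2,
                            "eta2": cond.eta2,
                            "chose_delayed": bool(rng.random() < p_delayed),
                        }
                    )
            else:  # adaptive_staircase
                est = adaptive_indifference(
                    value, X, beta, rng, n_steps=design.n_staircase_steps
                )
                indiff_rows.append(
                    {
                        "condition": cond.label,
                        "X": X,
                        "t": t,
                        "sigma2": cond.sigma2,
                        "eta2": cond.eta2,
                        "x_report": est,
                    }
                )
    data = SubjectData(
        subject_id=subject_id,
        indifference=pd.DataFrame(indiff_rows) if indiff_rows else None,
        choices=pd.DataFrame(choice_rows) if choice_rows else None,
    )
    return SubjectRecord(
        subject_id=subject_id,
        true_params=dict(true_params),
        data=data,
        predictions=pd.DataFrame(pred_rows),
        intervals=pd.DataFrame(interval_rows),
        seed=seed,
    )


def simulate_cohort(
    design: ExperimentDesign,
    population: PopulationSpec,
    n_subjects: int,
    seed: int,
) -> list[SubjectRecord]:
    """Simulate an i.i.d. cohort; same seed reproduces identical data."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for j in range(n_subjects):
        params = population.draw(rng)
        subj_seed = int(rng.integers(2**31 - 1))
        records.append(
            simulate_subject(params, design, subj_seed, subject_id=f"s{j:03d}")
        )
    return records


def weighted_condition_regression(
    logk_table: pd.DataFrame, coding: Optional[dict] = None
) -> dict:
    """Reliability-weighted regression of log K on condition code.

    ``logk_table`` has columns (subject, condition, logK, weight).
    Conditions are coded 0/1/2... (alphabetical order unless ``coding``
    maps labels to codes); log K is centered within subject before a
    weighted least-squares fit, approximating a mixed model with random
    intercepts.  Returns slope, SE, t and p.
    """
    df = logk_table.copy()
    if df["weight"].sum() <= 0:
        raise ValueError("total weight must be positive")
    if coding is None:
        labels = sorted(df["condition"].unique())
        coding = {lab: i for i, lab in enumerate(labels)}
    if len(coding) < 2:
        raise ValueError("need at least 2 conditions")
    df["code"] = df["condition"].map(coding).astype(float)
    df["logK_c"] = df["logK"] - df.groupby("subject")["logK"].transform("mean")
    df["code_c"] = df["code"] - df.groupby("subject")["code"].transform("mean")
    res = sm.WLS(df["logK_c"], sm.add_constant(df["code_c"]), weights=df["weight"]).fit()
    return {
        "slope": float(res.params["code_c"]),
        "se": float(res.bse["code_c"]),
        "t": float(res.tvalues["code_c"]),
        "p": float(res.pvalues["code_c"]),
        "n": int(len(df)),
    }


def _default_models(likelihood: str, fixed: Optional[dict] = None) -> list[ModelSpec]:
    extra = ("noise_sd",) if likelihood == "gaussian_indifference" else ("beta",)
    fixed = fixed or {}
    return [
        ModelSpec(
            name="volatility",
            value_model="volatility",
            likelihood=likelihood,
            free=("K", "m") + extra,
            fixed=fixed,
        ),
        ModelSpec(
            name="null",
            value_model="hyperbolic_null",
            likelihood=likelihood,
            free=("K",) + extra,
            fixed=fixed,
        ),
        ModelSpec(
            name="concave_utility",
            value_model="concave_utility",
            likelihood=likelihood,
            free=("K", "rho") + extra,
            fixed=fixed,
        ),
    ]


def _per_condition_logk(
    records: Sequence[SubjectRecord],
    design: ExperimentDesign,
    likelihood: str,
    seed: int,
) -> pd.DataFrame:
    """Per-subject per-condition log K fits with m = 0, with
    reliability weights from the observed information of log K."""
    rows = []
    extra = ("noise_sd",) if likelihood == "gaussian_indifference" else ("beta",)
    spec = ModelSpec(
        name="null_per_condition",
        value_model="hyperbolic_null",
        likelihood=likelihood,
        free=("K",) + extra,
    )
    for cond in design.conditions:
        subset = []
        for rec in records:
            d = rec.data
            subset.append(
                SubjectData(
                    subject_id=rec.subject_id,
                    indifference=None
                    if d.indifference is None
                    else d.indifference[d.indifference["condition"] == cond.label],
                    choices=None
                    if d.choices is None
                    else d.choices[d.choices["condition"] == cond.label],
                )
            )
        gfit = fit_group_em(subset, spec, seed=seed)
        weights = subject_reliability(gfit.subject_fits, "K")
        for f, w in zip(gfit.subject_fits, weights):
            rows.append(
                {
                    "subject": f.subject_id,
                    "condition": cond.label,
                    "logK": float(f.map_z[list(f.names).index("K")]),
                    "weight": float(w),
                }
            )
    return pd.DataFrame(rows)


def run_experiment_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Simulate a cohort and run the full analysis chain.

    ``config`` keys: design (packaged name or path), population (dict of
    PopulationSpec overrides), n_subjects, seed, and optional model /
    em settings.  Stages: simulate -> hierarchical fits of all models +
    BICi + exceedance probabilities -> per-condition log K fits ->
    reliability-weighted condition regression -> correlation of log m
    with log K.  Returns a dict of results; CSV tables and a JSON
    manifest are written to ``out_dir`` when given.
    """
    seed = int(config.get("seed", 0))
    design = ExperimentDesign.from_config(
        config["design"], **config.get("design_overrides", {})
    )
    population = PopulationSpec(**config.get("population", {}))
    n_subjects = int(config.get("n_subjects", 20))
    records = simulate_cohort(design, population, n_subjects, seed)
    dataset = [r.data for r in records]
    likelihood = (
        "bernoulli_logistic"
        if design.elicitation == "binary_set"
        else "gaussian_indifference"
    )
    models = _default_models(likelihood)
    em_kwargs = dict(config.get("em", {"max_iter": 12}))
    comparison = compare_models(
        dataset, models, seed=seed + 1, em_kwargs=em_kwargs,
        n_mc_samples=int(config.get("n_mc_samples", 300)),
    )
    logk_table = _per_condition_logk(records, design, likelihood, seed + 2)
    regression = weighted_condition_regression(logk_table)
    # log m (volatility model) vs log K (null model), across subjects
    vol_fit = fit_group_em(dataset, models[0], seed=seed + 3, **em_kwargs)
    idx_m = models[0].free.index("m")
    idx_k = models[0].free.index("K")
    log_m = np.array([f.map_z[idx_m] for f in vol_fit.subject_fits])
    log_k = np.array([f.map_z[idx_k] for f in vol_fit.subject_fits])
    r_p, p_p = pearsonr(log_m, log_k)
    r_s, p_s = spearmanr(log_m, log_k)
    results = {
        "design": design.name,
        "seed": seed,
        "n_subjects": n_subjects,
        "comparison": comparison,
        "logk_table": logk_table,
        "condition_regression": regression,
        "logm_logk_pearson": {"r": float(r_p), "p": float(p_p)},
        "logm_logk_spearman": {"rho": float(r_s), "p": float(p_s)},
        "records": records,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparison.to_frame().to_csv(out / "model_comparison.csv", index=False)
        logk_table.to_csv(out / "logk_by_condition.csv", index=False)
        truth = pd.DataFrame(
            [{"subject": r.subject_id, **r.true_params} for r in records]
        )
        truth.to_csv(out / "true_parameters.csv", index=False)
        manifest = {
            "design": design.name,
            "seed": seed,
            "n_subjects": n_subjects,
            "condition_regression": regression,
            "logm_logk_pearson": results["logm_logk_pearson"],
            "logm_logk_spearman": results["logm_logk_spearman"],
            "models": [m.name for m in models],
            "BICi": comparison.bici.tolist(),
            "exceedance": comparison.exceedance.tolist(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
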