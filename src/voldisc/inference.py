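"""Hierarchical model fitting, model evidence and model comparison.

Subject-level parameters are estimated as MAP values under a Gaussian
population prior in transformed space (log for positive parameters),
with the prior itself learned by expectation-maximization across
subjects (empirical Bayes): the E-step computes each subject's MAP and
a Laplace approximation to their posterior, the M-step re-estimates
the prior mean and SD from the posterior moments.  Model evidence is
the integrated BIC: each subject's likelihood is averaged over Monte
Carlo draws from the fitted prior, and the summed log marginal is
penalized by the number of prior hyperparameters.  Models are compared
with random-effects Bayesian model selection, yielding exceedance
probabilities via a variational Dirichlet posterior over model
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, log_ndtr, logsumexp
from scipy.stats import norm

from voldisc.discounting import power_utility_certainty_equivalent

__all__ = [
    "SubjectData",
    "ModelSpec",
    "GroupPrior",
    "SubjectFit",
    "GroupFit",
    "ComparisonResult",
    "negloglik_indifference",
    "negloglik_binary",
    "fit_subject_map",
    "fit_group_em",
    "integrated_bic",
    "exceedance_probabilities",
    "subject_reliability",
]

_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e8  # surrogate objective for non-finite predictions

# transform of each parameter between fitting (unconstrained) space and
# natural space; positive parameters are fitted on the log scale
_LOG_PARAMS = {"K", "m", "s", "rho", "noise_sd", "beta"}
_DEFAULT_PRIOR = {
    # transformed-space (mean, sd) used to initialize the EM prior
    "K": (-3.0, 2.0),
    "m": (-5.0, 2.0),
    "s": (0.0, 0.5),
    "c": (0.0, 2.0),
    "rho": (0.0, 0.7),
    "lam": (0.0, 0.5),
    "noise_sd": (0.0, 1.0),
    "beta": (0.0, 1.0),
}


def to_natural(name: str, z: float) -> float:
    return float(np.exp(z)) if name in _LOG_PARAMS else float(z)


def to_transformed(name: str, x: float) -> float:
    if name in _LOG_PARAMS:
        if x <= 0:
            raise ValueError(f"{name} must be > 0 on the natural scale")
        return float(np.log(x))
    return float(x)


@dataclass
class SubjectData:
    """One participant's trials across task phases.

    ``indifference``: reported immediate amounts at indifference, one
    row per report, columns (X, t, sigma2, eta2, condition, x_report)
    plus optionally X_individual / X_group for the two magnitude
    sources.  ``choices``: binary intertemporal choices with columns
    (x_immediate, X, t, sigma2, eta2, condition, chose_delayed).
    ``risk_choices``: optional lottery choices with columns
    (guaranteed, mean, variance, chose_lottery).
    """

    subject_id: str
    indifference: Optional[pd.DataFrame] = None
    choices: Optional[pd.DataFrame] = None
    risk_choices: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for df, cols in (
            (self.indifference, ("X", "t", "sigma2", "eta2", "x_report")),
            (self.choices, ("x_immediate", "X", "t", "sigma2", "eta2", "chose_delayed")),
            (self.risk_choices, ("guaranteed", "mean", "variance", "chose_lottery")),
        ):
            if df is None:
                continue
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"data table missing columns {missing}")
            if "t" in df.columns and (df["t"] < 0).any():
                raise ValueError("delays must be >= 0")

    @property
    def n_obs(self) -> int:
        return sum(
            0 if df is None else len(df)
            for df in (self.indifference, self.choices, self.risk_choices)
        )


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model variant.

    ``value_model``: one of {"volatility", "hyperbolic_null",
    "concave_utility", "mean_variance"} ("hyperbolic_null" is the
    volatility model with m fixed at 0).  ``likelihood``: how data are
    scored, {"gaussian_indifference", "bernoulli_logistic"}.
    ``free``: ordered free-parameter names; every other model parameter
    takes its value from ``fixed`` (natural scale).  ``x_source``
    selects the magnitude column ("X", "X_individual" or "X_group").
    ``choice_rule``: "logistic" (default) or "probit" link for binary
    choices.
    """

    name: str
    value_model: str = "volatility"
    likelihood: str = "gaussian_indifference"
    free: tuple[str, ...] = ("K", "m", "noise_sd")
    fixed: dict = field(default_factory=dict)
    x_source: str = "X"
    choice_rule: str = "logistic"

    def __post_init__(self) -> None:
        if self.value_model not in {
            "volatility",
            "hyperbolic_null",
            "concave_utility",
            "mean_variance",
        }:
            raise ValueError(f"unknown value model {self.value_model!r}")
        if self.likelihood not in {"gaussian_indifference", "bernoulli_logistic"}:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        for p in self.free:
            if p not in _DEFAULT_PRIOR:
                raise ValueError(f"unknown parameter {p!r}")

    @property
    def n_free(self) -> int:
        return len(self.free)

    def params_from_vector(self, z: np.ndarray) -> dict:
        """Natural-scale parameter dict from a transformed vector."""
        params = {
            "K": 0.0, "m": 0.0, "s": 1.0, "c": 0.0,
            "rho": 1.0, "lam": 0.0, "noise_sd": 1.0, "beta": 1.0,
        }
        params.update(self.fixed)
        if self.value_model == "hyperbolic_null":
            params["m"] = 0.0
        for name, zi in zip(self.free, z):
            params[name] = to_natural(name, zi)
        return params

    def default_prior(self) -> "GroupPrior":
        mu = np.array([_DEFAULT_PRIOR[p][0] for p in self.free])
        sd = np.array([_DEFAULT_PRIOR[p][1] for p in self.free])
        return GroupPrior(names=self.free, mean=mu, sd=sd)


@dataclass(frozen=True)
class GroupPrior:
    """Gaussian population prior in transformed space."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("prior SDs must be > 0")

    def logpdf(self, z: np.ndarray) -> float:
        return float(np.sum(norm.logpdf(z, self.mean, self.sd)))


@dataclass
class SubjectFit:
    """MAP fit of one subject under one model."""

    subject_id: str
    model: str
    names: tuple[str, ...]
    map_z: np.ndarray          # transformed space
    neg_log_posterior: float
    info_diag: np.ndarray      # observed information (per parameter)
    converged: bool
    n_obs: int

    @property
    def params(self) -> dict:
        return {n: to_natural(n, z) for n, z in zip(self.names, self.map_z)}

    @property
    def posterior_var(self) -> np.ndarray:
        """Laplace posterior variances (clipped to a sane range)."""
        info = np.where(self.info_diag > 1e-8, self.info_diag, 1e-8)
        return np.clip(1.0 / info, 1e-8, 1e4)


@dataclass
class GroupFit:
    """Empirical-Bayes group fit: fitted prior plus all subject fits."""

    model: ModelSpec
    prior: GroupPrior
    subject_fits: list
    n_iterations: int
    converged: bool


@dataclass
class ComparisonResult:
    """Random-effects model comparison across a model set."""

    model_names: list
    bici: np.ndarray
    log_evidence: np.ndarray   # subjects x models
    exceedance: np.ndarray
    best_counts: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.exceedance.sum(), 1.0, atol=1e-6):
            raise ValueError("exceedance probabilities must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "BICi": self.bici,
                "exceedance_probability": self.exceedance,
                "n_subjects_best_fit": self.best_counts,
            }
        )


def _magnitude(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    col = spec.x_source if spec.x_source in df.columns else "X"
    return df[col].to_numpy(dtype=float)


class _TrialArrays:
    """Per-subject trial columns as plain arrays, extracted once so the
    optimizer's inner loop never touches pandas."""

    __slots__ = ("X", "t", "sigma2", "eta2", "x_report", "x_immediate", "chose")

    def __init__(self, data: "SubjectData", spec: "ModelSpec"):
        if spec.likelihood == "gaussian_indifference":
            df = data.indifference
            if df is None or len(df) == 0:
                raise ValueError("subject has no indifference data")
            self.x_report = df["x_report"].to_numpy(dtype=float)
            self.x_immediate = self.chose = None
        else:
            df = data.choices
            if df is None or len(df) == 0:
                raise ValueError("subject has no binary-choice data")
            self.x_immediate = df["x_immediate"].to_numpy(dtype=float)
            self.chose = df["chose_delayed"].to_numpy(dtype=bool)
            self.x_report = None
        self.X = _magnitude(df, spec)
        self.t = df["t"].to_numpy(dtype=float)
        self.sigma2 = df["sigma2"].to_numpy(dtype=float)
        self.eta2 = df["eta2"].to_numpy(dtype=float)


def _nll_arrays(arr: _TrialArrays, params: dict, spec: "ModelSpec") -> float:
    if not all(np.isfinite(v) for v in params.values()):
        return _PENALTY
    try:
        pred = _predicted_value(arr.X, arr.t, arr.sigma2, arr.eta2, params, spec)
    except (ArithmeticError, OverflowError):
        return _PENALTY
    if not np.all(np.isfinite(pred)):
        return _PENALTY
    if spec.likelihood == "gaussian_indifference":
        sd = params["noise_sd"]
        resid = arr.x_report - pred
        return float(
            0.5 * len(resid) * (_LOG2PI + 2.0 * np.log(sd))
            + 0.5 * np.sum(resid**2) / sd**2
        )
    dv = params["beta"] * (pred - arr.x_immediate)
    sign = np.where(arr.chose, 1.0, -1.0)
    if spec.choice_rule == "probit":
        ll = log_ndtr(sign * dv)
    else:
        ll = -np.logaddexp(0.0, -sign * dv)
    return float(-np.sum(ll))


def _predicted_value(
    X: np.ndarray,
    t: np.ndarray,
    sigma2: np.ndarray,
    eta2: np.ndarray,
    params: dict,
    spec: ModelSpec,
) -> np.ndarray:
    """Model value of the delayed/risky option (the immediate-amount
    equivalent); the bias c is applied to risky/delayed rows only."""
    K, m, s, c = params["K"], params["m"], params["s"], params["c"]
    hyper = 1.0 / (1.0 + K * t**s)
    variance = sigma2 * t**s + eta2
    risky = (t > 0) | (variance > 0)
    if spec.value_model in ("volatility", "hyperbolic_null"):
        v = X * hyper / (1.0 + m * variance)
    elif spec.value_model == "concave_utility":
        # trials share few distinct (X, variance) pairs; deduplicate
        # before the quadrature
        pairs, inv = np.unique(X + 1j * variance, return_inverse=True)
        ce = power_utility_certainty_equivalent(
            pairs.real, pairs.imag, params["rho"]
        )
        v = np.asarray(ce)[inv] * hyper
    else:  # mean_variance
        v = (X - params["lam"] * variance) * hyper
    return v + np.where(risky, c, 0.0)


def negloglik_indifference(
    params: dict, data: SubjectData, model_spec: ModelSpec
) -> float:
    """Gaussian negative log likelihood of reported indifference amounts.

    Reports are modelled as the model-predicted indifference amount
    plus Gaussian noise with free SD ``noise_sd``.
    """
    df = data.indifference
    if df is None or len(df) == 0:
        raise ValueError("subject has no indifference data")
    X = _magnitude(df, model_spec)
    try:
        pred = _predicted_value(
            X,
            df["t"].to_numpy(dtype=float),
            df["sigma2"].to_numpy(dtype=float),
            df["eta2"].to_numpy(dtype=float),
            params,
            model_spec,
        )
    except (ArithmeticError, OverflowError):
        pred = np.full(len(df), np.nan)
    if not np.all(np.isfinite(pred)):
        warnings.warn("non-finite model prediction; penalizing", RuntimeWarning)
        return _PENALTY
    sd = params["noise_sd"]
    resid = df["x_report"].to_numpy(dtype=float) - pred
    return float(
        0.5 * len(resid) * (_LOG2PI + 2.0 * np.log(sd))
        + 0.5 * np.sum(resid**2) / sd**2
    )


def negloglik_binary(params: dict, data: SubjectData, model_spec: ModelSpec) -> float:
    """Bernoulli negative log likelihood of binary intertemporal choices.

    P(choose delayed) = link(beta * (V_delayed - x_immediate)) with a
    logistic (default) or probit link and inverse temperature beta.
    """
    df = data.choices
    if df is None or len(df) == 0:
        raise ValueError("subject has no binary-choice data")
    X = _magnitude(df, model_spec)
    try:
        v_delayed = _predicted_value(
            X,
            df["t"].to_numpy(dtype=float),
            df["sigma2"].to_numpy(dtype=float),
            df["eta2"].to_numpy(dtype=float),
            params,
            model_spec,
        )
    except (ArithmeticError, OverflowError):
        v_delayed = np.full(len(df), np.nan)
    if not np.all(np.isfinite(v_delayed)):
        warnings.warn("non-finite model prediction; penalizing", RuntimeWarning)
        return _PENALTY
    dv = params["beta"] * (v_delayed - df["x_immediate"].to_numpy(dtype=float))
    chose = df["chose_delayed"].to_numpy(dtype=bool)
    sign = np.where(chose, 1.0, -1.0)
    if model_spec.choice_rule == "probit":
        ll = log_ndtr(sign * dv)
    else:
        # log expit(x) = -log(1 + exp(-x)), stable form
        ll = -np.logaddexp(0.0, -sign * dv)
    return float(-np.sum(ll))


def _negloglik(z: np.ndarray, data: SubjectData, spec: ModelSpec) -> float:
    params = spec.params_from_vector(z)
    if spec.likelihood == "gaussian_indifference":
        return negloglik_indifference(params, data, spec)
    return negloglik_binary(params, data, spec)


def _hessian(fun, z: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Observed information (full Hessian) by central differences."""
    n = len(z)
    H = np.empty((n, n))
    f0 = fun(z)
    for i in range(n):
        zp, zm = z.copy(), z.copy()
        zp[i] += step
        zm[i] -= step
        H[i, i] = (fun(zp) - 2.0 * f0 + fun(zm)) / step**2
    for i in range(n):
        for j in range(i + 1, n):
            zpp, zpm, zmp, zmm = z.copy(), z.copy(), z.copy(), z.copy()
            zpp[[i, j]] += step
            zmm[[i, j]] -= step
            zpm[i] += step
            zpm[j] -= step
            zmp[i] -= step
            zmp[j] += step
            H[i, j] = H[j, i] = (
                fun(zpp) - fun(zpm) - fun(zmp) + fun(zmm)
            ) / (4.0 * step**2)
    return H


def _marginal_precisions(H: np.ndarray) -> np.ndarray:
    """Per-parameter precision = 1 / marginal posterior variance, from
    the inverse Hessian (falls back to the diagonal if not invertible)."""
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.all(np.isfinite(var)) and np.all(var > 0):
            return 1.0 / var
    except np.linalg.LinAlgError:
        pass
    d = np.diag(H).copy()
    return np.where(np.isfinite(d) & (d > 0), d, 0.0)


def fit_subject_map(
    data: SubjectData,
    model_spec: ModelSpec,
    prior: GroupPrior,
    seed: int = 0,
    n_starts: int = 5,
    extra_start: Optional[np.ndarray] = None,
) -> SubjectFit:
    """MAP estimate of one subject's parameters under a Gaussian prior.

    Minimizes NLL(z) - log prior(z) in transformed space from
    ``n_starts`` seeded starting points drawn around the prior (plus an
    optional warm start); returns the best optimum with the diagonal
    observed information at it.
    """
    rng = np.random.default_rng(seed)
    arrays = _TrialArrays(data, model_spec)
    inv_var = 1.0 / prior.sd**2
    log_norm = float(np.sum(np.log(prior.sd))) + 0.5 * len(prior.sd) * _LOG2PI

    def objective(z):
        nll = _nll_arrays(arrays, model_spec.params_from_vector(z), model_spec)
        dz = z - prior.mean
        return nll + 0.5 * float(np.sum(dz * dz * inv_var)) + log_norm

    if extra_start is not None and n_starts <= 1:
        # warm restart (EM sweeps after the first): one start suffices
        starts = [np.asarray(extra_start, dtype=float)]
    else:
        starts = [prior.mean.copy()]
        starts += list(
            prior.mean
            + prior.sd * rng.standard_normal((max(n_starts - 1, 0), len(prior.mean)))
        )
        if extra_start is not None:
            starts.append(np.asarray(extra_start, dtype=float))
    best = None
    for z0 in starts:
        # L-BFGS-B on the smooth objective; simplex fallback if a start
        # lands on the penalty plateau or fails to move
        res = minimize(objective, z0, method="L-BFGS-B")
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2 or not res.success:
            res_nm = minimize(
                objective,
                z0,
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 250 * len(z0)},
            )
            if res_nm.fun < res.fun:
                res = res_nm
        if best is None or res.fun < best.fun:
            best = res
    info = _marginal_precisions(_hessian(objective, best.x))
    info = np.where(np.isfinite(info) & (info > 0), info, 0.0)
    return SubjectFit(
        subject_id=data.subject_id,
        model=model_spec.name,
        names=model_spec.free,
        map_z=np.asarray(best.x, dtype=float),
        neg_log_posterior=float(best.fun),
        info_diag=info,
        converged=bool(np.isfinite(best.fun) and best.fun < _PENALTY / 2),
        n_obs=data.n_obs,
    )


def fit_group_em(
    dataset: Sequence[SubjectData],
    model_spec: ModelSpec,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-3,
    prior0: Optional[GroupPrior] = None,
    sd_floor: float = 1e-3,
) -> GroupFit:
    """Empirical-Bayes EM over a cohort.

    Alternates per-subject MAP fits (E-step, warm-started after the
    first sweep) with moment updates of the Gaussian prior (M-step,
    prior variance = mean Laplace posterior variance + between-subject
    variance of the MAPs) until the prior parameters move less than
    ``tol`` or ``max_iter`` sweeps.  Deterministic given ``seed``.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects for a group fit")
    prior = prior0 if prior0 is not None else model_spec.default_prior()
    fits: list[SubjectFit] = []
    warm: dict[str, np.ndarray] = {}
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        fits = []
        for j, subj in enumerate(dataset):
            fits.append(
                fit_subject_map(
                    subj,
                    model_spec,
                    prior,
                    seed=seed + 7919 * j,
                    n_starts=5 if n_it == 1 else 1,
                    extra_start=warm.get(subj.subject_id),
                )
            )
        ok = [f for f in fits if f.converged]
        if not ok:
            raise RuntimeError("no subject fit converged")
        if len(ok) < len(fits):
            warnings.warn(
                f"{len(fits) - len(ok)} subject fit(s) did not converge; "
                "excluded from prior update",
                RuntimeWarning,
            )
        maps = np.array([f.map_z for f in ok])
        pvars = np.array([f.posterior_var for f in ok])
        new_mean = maps.mean(axis=0)
        new_var = pvars.mean(axis=0) + maps.var(axis=0)
        new_sd = np.sqrt(new_var)
        if np.any(new_sd < sd_floor):
            warnings.warn("prior SD collapsed; floor applied", RuntimeWarning)
            new_sd = np.maximum(new_sd, sd_floor)
        delta = max(
            np.max(np.abs(new_mean - prior.mean)), np.max(np.abs(new_sd - prior.sd))
        )
        prior = GroupPrior(names=model_spec.free, mean=new_mean, sd=new_sd)
        warm = {f.subject_id: f.map_z for f in fits}
        if delta < tol:
            converged = True
            break
    return GroupFit(
        model=model_spec,
        prior=prior,
        subject_fits=fits,
        n_iterations=n_it,
        converged=converged,
    )


def subject_log_marginals(
    group_fit: GroupFit,
    dataset: Sequence[SubjectData],
    n_mc_samples: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo log marginal likelihood of each subject.

    Averages the likelihood over draws from the fitted group prior
    (log-sum-exp guarded)."""
    rng = np.random.default_rng(seed)
    prior, spec = group_fit.prior, group_fit.model
    draws = prior.mean + prior.sd * rng.standard_normal(
        (n_mc_samples, len(prior.mean))
    )
    out = np.empty(len(dataset))
    for j, subj in enumerate(dataset):
        arrays = _TrialArrays(subj, spec)
        lls = np.array(
            [-_nll_arrays(arrays, spec.params_from_vector(z), spec) for z in draws]
        )
        lls = np.where(np.isfinite(lls), lls, -_PENALTY)
        out[j] = logsumexp(lls) - np.log(n_mc_samples)
    return out


def integrated_bic(
    group_fit: GroupFit,
    dataset: Sequence[SubjectData],
    n_mc_samples: int = 400,
    seed: int = 0,
) -> float:
    """Integrated BIC: -2 * sum of subject log marginals, penalized by
    the number of prior hyperparameters (2 per free parameter) times
    log(total observations).  Lower is better."""
    logm = subject_log_marginals(group_fit, dataset, n_mc_samples, seed)
    n_total = sum(s.n_obs for s in dataset)
    n_hyper = 2 * group_fit.model.n_free
    return float(-2.0 * logm.sum() + n_hyper * np.log(n_total))


def exceedance_probabilities(
    log_evidence_matrix: np.ndarray, n_samples: int = 20_000, seed: int = 0
) -> np.ndarray:
    """Random-effects Bayesian model selection.

    Given a subjects x models matrix of log model evidences, runs the
    variational Dirichlet update on population model frequencies and
    returns the exceedance probability of each model (the posterior
    probability that its frequency is the largest), estimated by
    sampling the Dirichlet posterior.
    """
    L = np.asarray(log_evidence_matrix, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    n_subj, n_models = L.shape
    alpha0 = np.ones(n_models)
    alpha = alpha0.copy()
    for _ in range(200):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        beta = np.exp(log_u).sum(axis=0)
        alpha_new = alpha0 + beta
        if np.max(np.abs(alpha_new - alpha)) < 1e-8:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    phi = np.bincount(winners, minlength=n_models) / n_samples
    return phi


def subject_reliability(
    fits: Sequence[SubjectFit], parameter: str
) -> np.ndarray:
    """Reliability weights for one parameter across subjects.

    The weight is the observed information (inverse posterior variance)
    of the named transformed parameter, normalized to mean 1 across
    subjects; non-positive information yields weight 0 with a warning.
    """
    weights = np.empty(len(fits))
    for j, f in enumerate(fits):
        if parameter not in f.names:
            raise KeyError(f"parameter {parameter!r} not in fit {f.names}")
        info = f.info_diag[f.names.index(parameter)]
        if not np.isfinite(info) or info <= 0:
            warnings.warn(
                f"non-positive information for {f.subject_id}; weight 0",
                RuntimeWarning,
            )
            weights[j] = 0.0
        else:
            weights[j] = info
    total = weights.mean()
    if total <= 0:
        raise ValueError("all reliability weights are zero")
    return weights / total


def compare_models(
    dataset: Sequence[SubjectData],
    model_specs: Sequence[ModelSpec],
    seed: int = 0,
    n_mc_samples: int = 400,
    em_kwargs: Optional[dict] = None,
) -> ComparisonResult:
    """Fit every model hierarchically and compare them.

    Returns BICi per model, the subjects x models log-evidence matrix
    (subject log marginals), exceedance probabilities and best-fit
    counts."""
    em_kwargs = em_kwargs or {}
    n_models = len(model_specs)
    bici = np.empty(n_models)
    log_ev = np.empty((len(dataset), n_models))
    for k, spec in enumerate(model_specs):
        gfit = fit_group_em(dataset, spec, seed=seed + 101 * k, **em_kwargs)
        logm = subject_log_marginals(
            gfit, dataset, n_mc_samples=n_mc_samples, seed=seed + 101 * k + 1
        )
        n_total = sum(s.n_obs for s in dataset)
        log_ev[:, k] = logm
        bici[k] = float(-2.0 * logm.sum() + 2 * spec.n_free * np.log(n_total))
    phi = exceedance_probabilities(log_ev, seed=seed + 997)
    best = np.bincount(np.argmax(log_ev, axis=1), minlength=n_models)
    return ComparisonResult(
        model_names=[m.name for m in model_specs],
        bici=bici,
        log_evidence=log_ev,
        exceedance=phi,
        best_counts=best,
    )
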