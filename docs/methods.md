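# Methods

This note documents the models implemented in `voldisc`, the estimation
machinery, the synthetic-data generator, and the numerical and design
choices a user should know before trusting (or extending) the results.

## Generative reward environment

The environment is a scalar state-space model: a latent market price
R_t follows a driftless Gaussian random walk with volatility SD σ
(currency per √week), and the price observed on each weekly trial is
r_t = R_t + ε with i.i.d. emission noise of SD η. Under the unbounded
process the observed price at delay t has mean R_0 and variance
σ²t + η²; with a subjective time exponent s the time-dependent term
generalises to σ²tˢ.

Task prices are bounded. The published task descriptions state bounds
without a mechanism, so the simulator clips the latent walk to
[lower, upper] at every step and clips the observed price separately —
the simplest scheme consistent with prices "returning toward the
long-run average" near the bounds. Clipping breaks the linear-variance
identity, so every recovery harness and analytic check runs with
`bounded=False`, while the exercised task configurations keep bounds
on. Prices are kept continuous internally; rounding to £0.01 happens
only at CSV serialization.

Three task configurations ship with the package
(`voldisc/configs/*.yaml`):

| config | conditions (σ) | η | bounds | start | delays (weeks) |
|---|---|---|---|---|---|
| exp1 | 0, 1.5, 3.5 (assumed) | 3 (assumed) | 0–25 | 12.5 | 1, 4, 7, 12, 18 |
| exp2 | 0 (stable), 3.5 (volatile) | 2 | 0–50 | 25 | 0, 1, 4, 17 |
| exp3 | 0, 1.5, 3.5 | 3 | 0–40 | 20 | 1, 4, 9, 13 |

The exp1 σ/η values are not published for that design; the config marks
them as assumptions (mirroring the online replication's levels) and
exposes them as ordinary fields. Learning phases default to 240 trials.

## Valuation models

The combined discount model values a delayed/risky prospect of expected
magnitude X at

x = X · 1/(1 + K tˢ) · 1/(1 + m(η² + σ²tˢ)) + c.

One s is shared between the baseline and volatility factors. The bias
c is added to delayed or risky options only (zero for an immediate
certain option); in binary-choice likelihoods it therefore shifts the
delayed option's value. Setting t = 0 and η² to a lottery's variance
gives the risk model used for baseline lottery choices,
x = X/(1 + m η²) + c.

Two alternatives are provided for model comparison. The additive
mean–variance value is mean − λ·variance. The concave-utility
alternative uses power utility u(r) = r^ρ: the risky magnitude is
Gaussian with mean X and variance σ²tˢ + η², truncated at zero
(magnitudes are positive), its expected utility is computed by 24-node
Gauss–Hermite quadrature in log space (stable for any ρ), and the
certainty equivalent E[u]^(1/ρ) is then discounted hyperbolically. The
exact published form of the concave-utility comparison model is not
available; this CE-under-truncated-Gaussian construction is this
package's documented choice. Within the fitted parameter range the
quadrature CE matches a 10⁶-draw Monte-Carlo estimate to better than
0.01.

Parameters K, m, s, ρ, the report-noise SD and the choice inverse
temperature β are fitted on the log scale (positivity; group summaries
are conventionally reported as log K, log m); c and λ are unconstrained.

## Learning rates and state-space oracles

Agents track prices with a Rescorla–Wagner rule V ← V + α(r − V).
`fit_rw_alpha` minimizes squared error between the rule's one-step-ahead
predictions and a subject's stated predictions, with α searched on
[0, 1] by bounded scalar minimization from five bracketed starts plus
explicit endpoint checks (tolerance 1e−6). The filter initializes at
the first observed price by default (`v0="first_price"`); a fitted or
fixed v0 is available. Fewer than three prediction trials is an error.

`optimal_alpha` applies the same criterion to the observed prices
themselves — the α minimizing one-step squared prediction error for a
given price process — averaged over seeded simulated series. Two
independent oracles validate it: the steady-state Kalman gain
(fixed point of the scalar Riccati recursion, iterated to |ΔP| < 1e−12),
which it matches within 0.02 on unbounded walks, and exact Kalman-filter
maximum likelihood (`fit_state_space_mle`), which recovers σ and η from
simulated unbounded sequences. The Kalman filter uses the known initial
price as its prior mean with zero prior variance, matching the
simulator's convention that the first stored latent value has received
one innovation from the start price.

## Subjective future uncertainty

Participants report 90% intervals for the price at several delays.
Under the random-walk model the half-width at delay t is
z·√(σ²t + θ₀²) with z = 1.6449 (two-sided Gaussian, configurable
coverage). `fit_sfu` regresses squared half-widths (divided by z²) on
delay: the slope is the subject's implied volatility σ̂² (the SFU) and
the intercept a time-independent uncertainty θ̂₀², both clipped at zero.
Fitting squared half-widths rather than widths makes the noise-free
problem exactly linear and hence exactly invertible, which is what the
acceptance check exploits; a likelihood-based fit on widths would weight
noise differently but estimate the same quantities. Asymmetric reports
are symmetrized via (upper − lower)/2. All-zero-width report sets (a
subject who never adjusted the interval) and single-delay designs raise
errors rather than returning degenerate fits. A time exponent is not
fitted (s = 1). Best-guess growth is summarised by a + b·log(1 + t),
with the ordinary linear slope reported for flatness checks.

## Hierarchical inference and model comparison

Subject parameters are estimated as MAP values in transformed space
under a Gaussian population prior, learned by empirical-Bayes EM:

- E-step: per-subject MAP by L-BFGS-B (Nelder–Mead fallback if a start
  lands on the penalty plateau), five seeded starts around the prior on
  the first sweep, a single warm start thereafter. The Laplace
  posterior uses the full observed-information matrix (central
  differences, step 1e−4); per-parameter posterior variances are the
  diagonal of its inverse, which matters because K and m are correlated
  in the likelihood.
- M-step: prior mean = mean of MAPs; prior variance = mean Laplace
  posterior variance + between-subject variance of MAPs; SD floor 1e−3.
- Convergence: prior parameters move < 1e−3, cap 50 sweeps.

Likelihoods: Gaussian for stated indifference amounts (free noise SD),
Bernoulli for binary choices with P(delayed) = logistic(β·ΔV) (probit
available by config). Non-finite model predictions are penalized with
a large finite objective value so the optimizer can retreat. Noise
parameters are shared within, not across, models.

Model evidence is the integrated BIC: each subject's likelihood is
averaged over Monte-Carlo draws from the fitted prior (log-sum-exp
guarded; 300–400 draws by default), and −2·Σ log marginals is penalized
by 2 hyperparameters per free parameter times log(total observations).
Models are compared by random-effects Bayesian model selection: a
variational Dirichlet posterior over population model frequencies,
with exceedance probabilities φ estimated from 20,000 Dirichlet draws.
Reliability weights for regressions on per-condition log K are the
observed information of log K, normalized to mean 1 across subjects.
The per-condition effect of volatility on log K is tested by
reliability-weighted least squares on subject-mean-centered log K and
condition code — an approximation to a random-intercept mixed model,
not a full random-slope fit.

## Synthetic cohorts

`simulate_subject` generates one agent end-to-end: learning-phase
prices and RW predictions (the agent's α, plus prediction noise),
interval reports with half-width z·√(sfu_scale²·σ²t + η²) plus width
noise (sfu_scale = 1 is veridical; ≠ 1 emulates miscalibrated
uncertainty), and valuation data through the agent's discount
parameters. Elicitation follows the design: direct indifference
reports (value + Gaussian report noise), binary choice sets (a
geometric grid of 7 immediate amounts in (0.15X, X] per delay, chosen
to bracket a plausible range of discount rates; the published choice
set is not available), or a 6-step bisection staircase driven by the
agent's logistic choice rule (resolution range/2⁶; a deterministic
agent converges to its true indifference within that resolution).

Population defaults are anchored where group values are known — log m ~
Normal(−7.44, 1), matching the measured group mean risk aversion — and
otherwise set to values typical of weekly-horizon discounting work:
log K ~ Normal(−3, 1) (median K ≈ 0.05/week), s ≈ 1 (log-normal,
SD 0.05), c ~ Normal(0, 0.25), α ~ Beta(6, 3), report noise £1,
interval-width noise £0.5, β = 2. An optional correlation between
log K and log m generates the individual-difference structure the
analysis pipeline is designed to detect.

What the generator does *not* emulate: attention lapses, asymmetric or
anchored interval reports, sequence effects, magnitude effects, and
subjective price predictions that deviate from the veridical flat
expectation (X is the start price). Passing recovery tests therefore
show the estimators are consistent under the model's own assumptions,
not that real participants satisfy them.

## Problem sizes and determinism

Recovery and selection harnesses run at desk scale: 20 subjects × 40
indifference reports per cohort (report noise £1), 8 pooled replicate
cohorts for the recovery correlation, 20 cohorts for model-selection
accuracy, 200 simulated series for learning-rate and state-space
summaries. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances. Every stochastic step takes an explicit
seed; identical seeds reproduce byte-identical simulation, fit and
comparison outputs, and the CLI records its seed in every manifest.

## Known limitations

- The EM prior update uses Laplace posteriors; for weakly identified
  subjects (small m) the posterior is prior-dominated and individual
  estimates shrink to the group mean, attenuating true-vs-recovered
  correlations at low m.
- BICi values depend on the Monte-Carlo draw count; comparisons should
  use the same count per model (as `compare_models` does).
- The bounded walk's moments have no closed form; quantitative checks
  against analytic moments require `bounded=False`.
- The mean–variance alternative is implemented for risk (t = 0) designs
  and discounts its value hyperbolically for t > 0; other temporal
  extensions are possible but not provided.
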