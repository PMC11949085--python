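"""Subject-level likelihoods, hierarchical EM, evidence, BMS."""

import numpy as np
import pandas as pd
import pytest

from voldisc.discounting import ConditionSpec, DiscountParams, indifference_amount
from voldisc.inference import (
    GroupPrior,
    ModelSpec,
    SubjectData,
    exceedance_probabilities,
    fit_group_em,
    fit_subject_map,
    negloglik_binary,
    negloglik_indifference,
    subject_log_marginals,
    subject_reliability,
)

COND = ConditionSpec(sigma2=12.25, eta2=0.0, label="high")


def make_indiff_subject(K, m, noise_sd, rng, sid="s0", n_reps=3,
                        sigma2s=(0.0, 2.25, 12.25), delays=(1, 4, 7, 12, 18)):
    rows = []
    params = DiscountParams(K=K, m=m, s=1.0, c=0.0)
    for s2 in sigma2s:
        cond = ConditionSpec(sigma2=s2, eta2=0.0)
        for t in delays:
            val = indifference_amount(25.0, t, params, cond)
            for _ in range(n_reps):
                rows.append(
                    {"X": 25.0, "t": float(t), "sigma2": s2, "eta2": 0.0,
                     "x_report": val + rng.normal(0, noise_sd)}
                )
    return SubjectData(subject_id=sid, indifference=pd.DataFrame(rows))


GAUSS_SPEC = ModelSpec(name="volatility", free=("K", "m", "noise_sd"),
                       fixed={"s": 1.0, "c": 0.0})


class TestNegloglikIndifference:
    def test_zero_residuals_value(self, rng):
        subj = make_indiff_subject(0.05, 0.0, 0.0, rng, n_reps=1)
        n = len(subj.indifference)
        params = {"K": 0.05, "m": 0.0, "s": 1.0, "c": 0.0, "noise_sd": 2.0}
        nll = negloglik_indifference(params, subj, GAUSS_SPEC)
        assert nll == pytest.approx(n * np.log(2.0 * np.sqrt(2 * np.pi)), rel=1e-9)

    def test_larger_residuals_increase_nll(self, rng):
        subj = make_indiff_subject(0.05, 1e-3, 1.0, rng)
        good = {"K": 0.05, "m": 1e-3, "s": 1.0, "c": 0.0, "noise_sd": 1.0}
        bad = dict(good, K=0.5)
        assert negloglik_indifference(bad, subj, GAUSS_SPEC) > negloglik_indifference(
            good, subj, GAUSS_SPEC
        )

    def test_generating_params_beat_perturbed_on_average(self, rng):
        wins = 0
        for _ in range(20):
            subj = make_indiff_subject(0.05, 6e-4, 1.0, rng)
            good = {"K": 0.05, "m": 6e-4, "s": 1.0, "c": 0.0, "noise_sd": 1.0}
            bad = dict(good, K=0.1, noise_sd=1.5)
            wins += negloglik_indifference(good, subj, GAUSS_SPEC) < (
                negloglik_indifference(bad, subj, GAUSS_SPEC)
            )
        assert wins >= 15


class TestNegloglikBinary:
    def make_choice_subject(self, rng, beta=2.0, K=0.05, n=40):
        rows = []
        params = DiscountParams(K=K, m=0.0, s=1.0, c=0.0)
        for _ in range(n):
            t = rng.choice([0.0, 1.0, 4.0, 17.0])
            x_imm = rng.uniform(5, 25)
            v = indifference_amount(25.0, t, params, ConditionSpec(0.0, 0.0))
            p = 1 / (1 + np.exp(-beta * (v - x_imm)))
            rows.append({"x_immediate": x_imm, "X": 25.0, "t": t,
                         "sigma2": 0.0, "eta2": 0.0,
                         "chose_delayed": bool(rng.random() < p)})
        return SubjectData(subject_id="c0", choices=pd.DataFrame(rows))

    def test_zero_temperature_gives_log2_per_trial(self, rng):
        subj = self.make_choice_subject(rng)
        spec = ModelSpec(name="null", value_model="hyperbolic_null",
                         likelihood="bernoulli_logistic", free=("K", "beta"))
        params = {"K": 0.05, "m": 0.0, "s": 1.0, "c": 0.0, "beta": 1e-12}
        nll = negloglik_binary(params, subj, spec)
        assert nll == pytest.approx(len(subj.choices) * np.log(2), rel=1e-6)

    def test_probit_and_logit_agree_at_indifference(self, rng):
        subj = self.make_choice_subject(rng, n=10)
        subj.choices["x_immediate"] = 25.0 / (1 + 0.05 * subj.choices["t"])
        params = {"K": 0.05, "m": 0.0, "s": 1.0, "c": 0.0, "beta": 2.0}
        for rule in ("logistic", "probit"):
            spec = ModelSpec(name="n", value_model="hyperbolic_null",
                             likelihood="bernoulli_logistic", free=("K", "beta"),
                             choice_rule=rule)
            # value difference is 0 on every trial: P = 0.5 either way
            assert negloglik_binary(params, subj, spec) == pytest.approx(
                len(subj.choices) * np.log(2), rel=1e-9
            )

    def test_choice_recovery(self, rng):
        spec = ModelSpec(name="null", value_model="hyperbolic_null",
                         likelihood="bernoulli_logistic", free=("K", "beta"))
        prior = GroupPrior(names=("K", "beta"), mean=np.array([-3.0, 0.5]),
                           sd=np.array([2.0, 1.0]))
        est = []
        for i in range(10):
            subj = self.make_choice_subject(rng, K=0.08, n=60)
            fit = fit_subject_map(subj, spec, prior, seed=i)
            est.append(np.exp(fit.map_z[0]))
        assert np.mean(est) == pytest.approx(0.08, abs=0.03)


class TestFitSubjectMAP:
    def test_tight_prior_dominates(self, rng):
        subj = make_indiff_subject(0.05, 1e-3, 1.0, rng)
        prior = GroupPrior(names=GAUSS_SPEC.free,
                           mean=np.array([-2.0, -6.0, 0.5]),
                           sd=np.array([1e-4, 1e-4, 1e-4]))
        fit = fit_subject_map(subj, GAUSS_SPEC, prior, seed=0)
        assert np.allclose(fit.map_z, prior.mean, atol=1e-3)

    def test_flat_prior_approaches_mle(self, rng):
        subj = make_indiff_subject(0.05, 0.0, 0.2, rng, n_reps=4)
        spec = ModelSpec(name="null", value_model="hyperbolic_null",
                         free=("K", "noise_sd"))
        prior = GroupPrior(names=spec.free, mean=np.array([-3.0, 0.0]),
                           sd=np.array([50.0, 50.0]))
        fit = fit_subject_map(subj, spec, prior, seed=0)
        assert np.exp(fit.map_z[0]) == pytest.approx(0.05, rel=0.05)

    def test_calibration_map_near_truth(self, rng):
        """MAP lands within 2 posterior SDs of truth in most replicates."""
        prior = GroupPrior(names=GAUSS_SPEC.free,
                           mean=np.array([-3.0, -7.4, 0.0]),
                           sd=np.array([1.0, 1.0, 0.5]))
        hits = np.zeros(3)
        n_rep = 30
        for i in range(n_rep):
            true_z = prior.mean + prior.sd * rng.standard_normal(3)
            subj = make_indiff_subject(np.exp(true_z[0]), np.exp(true_z[1]),
                                       np.exp(true_z[2]), rng, sid=f"r{i}")
            fit = fit_subject_map(subj, GAUSS_SPEC, prior, seed=i)
            sd = np.sqrt(fit.posterior_var)
            hits += np.abs(fit.map_z - true_z) <= 2 * sd + 1e-6
        # per-parameter coverage of the 2-SD Laplace interval
        assert np.all(hits >= 0.85 * n_rep)


class TestGroupEM:
    def test_permuting_subjects_leaves_fit_unchanged(self, rng):
        subjects = [
            make_indiff_subject(0.05 * (1 + i / 4), 6e-4, 1.0, rng, sid=f"s{i}")
            for i in range(4)
        ]
        g1 = fit_group_em(subjects, GAUSS_SPEC, seed=0, max_iter=5)
        g2 = fit_group_em(subjects[::-1], GAUSS_SPEC, seed=0, max_iter=5)
        assert np.allclose(g1.prior.mean, g2.prior.mean, atol=1e-6)
        assert np.allclose(g1.prior.sd, g2.prior.sd, atol=1e-6)

    def test_identical_subjects_shrink_prior(self, rng):
        base = make_indiff_subject(0.05, 6e-4, 0.5, rng)
        subjects = [
            SubjectData(subject_id=f"s{i}", indifference=base.indifference.copy())
            for i in range(4)
        ]
        gfit = fit_group_em(subjects, GAUSS_SPEC, seed=0, max_iter=15)
        maps = np.array([f.map_z for f in gfit.subject_fits])
        assert np.allclose(maps.std(axis=0), 0.0, atol=1e-4)
        # between-subject spread of the prior collapses toward the
        # within-subject posterior SD
        assert np.all(gfit.prior.sd < 1.0)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_group_em([make_indiff_subject(0.05, 0.0, 1.0, rng)], GAUSS_SPEC)


class TestEvidence:
    def test_duplicate_subjects_double_likelihood_term(self, rng):
        subjects = [
            make_indiff_subject(0.05, 6e-4, 1.0, rng, sid=f"s{i}") for i in range(3)
        ]
        gfit = fit_group_em(subjects, GAUSS_SPEC, seed=0, max_iter=5)
        logm = subject_log_marginals(gfit, subjects, n_mc_samples=500, seed=1)
        logm2 = subject_log_marginals(gfit, subjects + subjects,
                                      n_mc_samples=500, seed=1)
        assert logm2.sum() == pytest.approx(2 * logm.sum(), rel=1e-9)

    def test_integrated_bic_consistent_with_marginals(self, rng):
        from voldisc.inference import integrated_bic

        subjects = [
            make_indiff_subject(0.05, 6e-4, 1.0, rng, sid=f"s{i}") for i in range(3)
        ]
        gfit = fit_group_em(subjects, GAUSS_SPEC, seed=0, max_iter=5)
        logm = subject_log_marginals(gfit, subjects, n_mc_samples=200, seed=4)
        bici = integrated_bic(gfit, subjects, n_mc_samples=200, seed=4)
        n_total = sum(s.n_obs for s in subjects)
        expected = -2 * logm.sum() + 2 * 3 * np.log(n_total)
        assert bici == pytest.approx(expected, rel=1e-12)

    def test_extra_parameter_penalized_on_null_data(self, rng):
        """On data generated with m = 0, the volatility model's extra
        parameter usually costs more evidence than it buys."""
        from voldisc.inference import integrated_bic

        null_spec = ModelSpec(name="null", value_model="hyperbolic_null",
                              free=("K", "noise_sd"), fixed={"s": 1.0, "c": 0.0})
        wins = 0
        n_cohorts = 8
        for c in range(n_cohorts):
            subjects = [
                make_indiff_subject(
                    np.exp(-3 + 0.5 * rng.standard_normal()), 0.0, 1.0, rng,
                    sid=f"s{i}",
                )
                for i in range(6)
            ]
            b = {}
            for spec in (null_spec, GAUSS_SPEC):
                gfit = fit_group_em(subjects, spec, seed=c, max_iter=6)
                b[spec.name] = integrated_bic(gfit, subjects,
                                              n_mc_samples=300, seed=c)
            wins += b["null"] < b["volatility"]
        assert wins >= 0.7 * n_cohorts

    def test_mc_estimate_stabilizes_with_samples(self, rng):
        subjects = [
            make_indiff_subject(0.05, 6e-4, 1.0, rng, sid=f"s{i}") for i in range(3)
        ]
        gfit = fit_group_em(subjects, GAUSS_SPEC, seed=0, max_iter=5)

        def spread(n_mc):
            vals = [
                subject_log_marginals(gfit, subjects, n_mc, seed=s).sum()
                for s in range(6)
            ]
            return np.std(vals)

        assert spread(1600) < spread(50)


class TestExceedance:
    def test_symmetric_evidence_splits_evenly(self):
        L = np.zeros((10, 2))
        phi = exceedance_probabilities(L, n_samples=40_000, seed=0)
        assert phi.sum() == pytest.approx(1.0)
        assert phi[0] == pytest.approx(0.5, abs=0.02)

    def test_dominant_model_wins(self):
        L = np.zeros((20, 2))
        L[:, 0] = 3.0  # better by 3 log units for every subject
        phi = exceedance_probabilities(L, n_samples=20_000, seed=0)
        assert phi[0] > 0.99

    def test_sums_to_one_and_permutation_invariant(self, rng):
        L = rng.normal(size=(15, 3))
        phi = exceedance_probabilities(L, n_samples=20_000, seed=5)
        assert phi.sum() == pytest.approx(1.0)
        perm = [2, 0, 1]
        phi_p = exceedance_probabilities(L[:, perm], n_samples=20_000, seed=5)
        assert np.allclose(phi_p, phi[perm], atol=0.02)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            exceedance_probabilities(np.zeros((5, 1)))


class TestReliability:
    def test_more_observations_more_weight(self, rng):
        prior = GroupPrior(names=GAUSS_SPEC.free,
                           mean=np.array([-3.0, -7.4, 0.0]),
                           sd=np.array([1.0, 1.0, 0.5]))
        small = make_indiff_subject(0.05, 6e-4, 1.0, rng, sid="small", n_reps=1)
        big = make_indiff_subject(0.05, 6e-4, 1.0, rng, sid="big", n_reps=4)
        fits = [fit_subject_map(s, GAUSS_SPEC, prior, seed=0) for s in (small, big)]
        w = subject_reliability(fits, "K")
        assert w[1] > w[0]
        assert w.mean() == pytest.approx(1.0)

    def test_weights_deterministic(self, rng):
        prior = GroupPrior(names=GAUSS_SPEC.free,
                           mean=np.array([-3.0, -7.4, 0.0]),
                           sd=np.array([1.0, 1.0, 0.5]))
        fits = [
            fit_subject_map(
                make_indiff_subject(0.05, 6e-4, 1.0, rng, sid=f"s{i}"),
                GAUSS_SPEC, prior, seed=i,
            )
            for i in range(3)
        ]
        assert np.array_equal(subject_reliability(fits, "m"),
                              subject_reliability(fits, "m"))


class TestVolatilityRescalingIdentity:
    def test_fit_at_one_sigma_predicts_another(self):
        """With eta^2 = 0, (K, m) at volatility sigma^2 is equivalent to
        (K, m * sigma^2 / sigma'^2) at volatility sigma'^2."""
        params1 = DiscountParams(K=0.05, m=6e-4, s=1.0, c=0.0)
        cond1 = ConditionSpec(sigma2=12.25, eta2=0.0)
        params2 = DiscountParams(K=0.05, m=6e-4 * 12.25 / 2.25, s=1.0, c=0.0)
        cond2 = ConditionSpec(sigma2=2.25, eta2=0.0)
        for t in (0.0, 1.0, 4.0, 18.0):
            assert indifference_amount(25.0, t, params1, cond1) == pytest.approx(
                indifference_amount(25.0, t, params2, cond2), rel=1e-12
            )
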