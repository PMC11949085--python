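import numpy as np
import pytest

from voldisc.cohort import ExperimentDesign, PopulationSpec, simulate_cohort
from voldisc.discounting import ConditionSpec
from voldisc.generative import RandomWalkSpec


@pytest.fixture(scope="session")
def exp2_volatile_spec() -> RandomWalkSpec:
    """The scanner task's volatile product: sigma 3.5, eta 2, bounds 0-50."""
    return RandomWalkSpec(sigma=3.5, eta=2.0, r0=25.0, lower=0.0, upper=50.0,
                          n_trials=240)


@pytest.fixture(scope="session")
def recovery_design() -> ExperimentDesign:
    """Direct-indifference design at the study's volatility levels
    (sigma in {0, 1.5, 3.5}), five delays, eta^2 = 0 at sale."""
    conds = tuple(
        ConditionSpec(sigma2=s**2, eta2=0.0, label=lab)
        for s, lab in [(0.0, "none"), (1.5, "low"), (3.5, "high")]
    )
    walks = tuple(
        RandomWalkSpec(sigma=s, eta=2.0, r0=25.0, lower=0.0, upper=50.0)
        for s in (0.0, 1.5, 3.5)
    )
    return ExperimentDesign(
        name="recovery",
        conditions=conds,
        walk_specs=walks,
        delays=(1.0, 4.0, 7.0, 12.0, 18.0),
        elicitation="direct_indifference",
        n_reports_per_cell=3,
        n_prediction_trials=5,
    )


@pytest.fixture(scope="session")
def recovery_population() -> PopulationSpec:
    """Cohort generator anchored at the measured group risk aversion
    (mean log m = -7.44 rounded to -7.4 for the recovery harness),
    report noise 1 pound, and near-degenerate s and c so the fitted
    three-parameter model matches the generator."""
    return PopulationSpec(
        mu_log_m=-7.4,
        sd_log_m=1.0,
        mu_log_k=-3.0,
        sd_log_k=1.0,
        sd_log_s=0.01,
        mu_c=0.0,
        sd_c=0.01,
        report_noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def small_cohort(recovery_design, recovery_population):
    """Six-subject cohort reused by cheap integration tests."""
    return simulate_cohort(recovery_design, recovery_population, 6, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
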