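import numpy as np
import pytest

from nsclc_cea import (
    DecisionModel,
    PseudoIPD,
    SimSpec,
    base_case_model,
    digitize,
    simulate_trial,
)


@pytest.fixture(scope="session")
def model() -> DecisionModel:
    return base_case_model()


@pytest.fixture(scope="session")
def sim_spec() -> SimSpec:
    # noise-free digitization of a moderately sized arm; fixed seed
    return SimSpec(n_per_arm=154, dropout_rate=0.0, coord_decimals=10, seed=7)


@pytest.fixture(scope="session")
def sim_ipd(sim_spec) -> PseudoIPD:
    return simulate_trial(sim_spec, "os")


@pytest.fixture(scope="session")
def sim_digitized(sim_spec, sim_ipd):
    return digitize(sim_ipd, sim_spec)


@pytest.fixture(scope="session")
def big_weibull_sample() -> PseudoIPD:
    # the hazard-scale lambda is noisy (sd of ln(lambda-hat) ~ 3/sqrt(n)),
    # so tight recovery bounds need a large sample
    spec = SimSpec(
        n_per_arm=20_000, dropout_rate=0.0, admin_censor_time=1e9, seed=11
    )
    return simulate_trial(spec, "os")
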