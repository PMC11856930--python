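import numpy as np
import pytest

from avrecal import (CausalPrior, MeasurementModel, ModelSpec, ObserverParams,
                     simulate_experiment)


@pytest.fixture
def model():
    """Asymmetric measurement model with a small positive bias."""
    return MeasurementModel(bias=0.03, tau_a=0.06, tau_v=0.07)


@pytest.fixture
def symmetric_model():
    return MeasurementModel(bias=0.0, tau_a=0.05, tau_v=0.05)


@pytest.fixture
def prior():
    return CausalPrior(sigma_c1=0.05, sigma_c2=0.8, p_common=0.6)


@pytest.fixture
def ci_ms_spec():
    return ModelSpec.from_code("ci_ms")


@pytest.fixture
def ci_observer():
    return ObserverParams(beta_pre=0.03, tau_a=0.05, tau_v=0.09,
                          criterion=0.08, lapse=0.02, alpha=0.01,
                          sigma_c1=0.05, sigma_c2=0.8, p_common=0.6)


@pytest.fixture(scope="session")
def ci_dataset():
    """One full nine-session experiment from a causal-inference observer."""
    spec = ModelSpec.from_code("ci_ms")
    observer = ObserverParams(beta_pre=0.03, tau_a=0.05, tau_v=0.09,
                              criterion=0.08, lapse=0.02, alpha=0.01,
                              sigma_c1=0.05, sigma_c2=0.8, p_common=0.6)
    return simulate_experiment(spec, observer, rng_seed=101)


def random_measurement_models(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield MeasurementModel(bias=rng.uniform(-0.3, 0.3),
                               tau_a=rng.uniform(1e-3, 1.0),
                               tau_v=rng.uniform(1e-3, 1.0))
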