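import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import broilerne as b

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    return b.published_truth(seed=0)


@pytest.fixture(scope="session")
def noise_free_truth():
    t = b.published_truth(seed=0)
    t.noise_cvs = {k: 0.0 for k in t.noise_cvs}
    return t


@pytest.fixture(scope="session")
def noise_free_results(noise_free_truth):
    model = b.NetEnergyStudy.from_synthetic(truth=noise_free_truth, seed=7)
    return model.fit(fit_equations=False, anova=False)


@pytest.fixture(scope="session")
def noisy_results():
    model = b.NetEnergyStudy.from_synthetic(seed=11)
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
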