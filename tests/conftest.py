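import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glca import ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params_n2() -> ModelParams:
    """The two-alternative recovery configuration."""
    return ModelParams(kappa=4.0, beta=1.0, inputs=(0.9, 1.1), xi=0.25)


@pytest.fixture
def params_n3() -> ModelParams:
    """The three-alternative recovery configuration."""
    return ModelParams(kappa=4.0, beta=1.0, inputs=(0.9, 1.1, 0.98), xi=0.25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def scalar_ou_mean_var(x0, tau, rate, level, sigma):
    """Conditional mean/variance of the scalar mean-reverting Gaussian
    diffusion dx = (rate*level - rate*x) dt + sigma dW — the independent
    oracle for the decoupled and difference-process reductions."""
    decay = np.exp(-rate * tau)
    mean = x0 * decay + level * (1.0 - decay)
    var = sigma**2 * (1.0 - np.exp(-2.0 * rate * tau)) / (2.0 * rate)
    return mean, var


def scalar_ou_logpdf(x, x0, tau, rate, level, sigma):
    mean, var = scalar_ou_mean_var(x0, tau, rate, level, sigma)
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)
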