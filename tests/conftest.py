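import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vakinetics as vk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec1():
    return vk.ModelSpec(variant=vk.Variant.ONE_EV)


@pytest.fixture(scope="session")
def spec2():
    return vk.ModelSpec(variant=vk.Variant.TWO_EV)


@pytest.fixture(scope="session")
def spec2_di():
    return vk.ModelSpec(variant=vk.Variant.TWO_EV, include_diet_constraint=True)


@pytest.fixture(scope="session")
def us_params():
    return vk.template_params(vk.GroupTemplate.US_LIKE)


@pytest.fixture(scope="session")
def ch_params():
    return vk.template_params(vk.GroupTemplate.CHINESE_LIKE)


@pytest.fixture(scope="session")
def one_ev_params():
    """Plausible one-pool kinetics: fractional loss 1.6%/d, M6/M5 ~ 157."""
    return vk.KineticParameters.from_dict({
        "L_2_1": 1.2, "L_3_2": 5.0, "DT_3": 0.1, "L_5_4": 2.5,
        "L_6_5": 4.07, "L_5_6": 0.01, "L_10_6": 0.016,
    })


@pytest.fixture(scope="session")
def cohort():
    return vk.load_cohort()


def lognormal_noise(rng: np.random.Generator, size: int, cv: float = 0.05):
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return np.exp(rng.normal(0.0, sigma, size))
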