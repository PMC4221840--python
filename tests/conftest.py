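import warnings

import pytest

from waxgc import (
    SimulationConfig,
    builtin_profile,
    default_rt_model,
    generate_run,
)


@pytest.fixture(scope="session")
def rt_model():
    return default_rt_model()


def make_run(profile_name: str, noise_sd: float = 0.01, seed: int = 7, **kwargs):
    profile = builtin_profile(profile_name)
    config = SimulationConfig(noise_sd=noise_sd, seed=seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # builtin profiles must fit the scan window
        return generate_run(profile, config)


@pytest.fixture(scope="session")
def carnauba_run():
    return make_run("carnauba")


@pytest.fixture(scope="session")
def carnauba_noiseless():
    return make_run("carnauba", noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def rice_bran_run():
    return make_run("rice_bran")


@pytest.fixture(scope="session")
def urushi_run():
    return make_run("urushi")


@pytest.fixture(scope="session")
def japan_wax_run():
    return make_run("japan_wax")


@pytest.fixture(scope="session")
def candelilla_run():
    return make_run("candelilla")
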