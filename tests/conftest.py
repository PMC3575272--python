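import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import posturefb as pf
from posturefb.fixtures import STUDY_SUBJECT, default_study_fixture, \
    demo_controller

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def body():
    return pf.derive_body_params(STUDY_SUBJECT)


@pytest.fixture(scope="session")
def engine(body):
    return pf.DynamicsEngine(body)


@pytest.fixture(scope="session")
def demo_ctrl(body):
    return demo_controller(body)


@pytest.fixture(scope="session")
def study_fixtures():
    """Ground-truth study scenarios (90/180/225 deg), dt = 2 ms."""
    return default_study_fixture()


@pytest.fixture(scope="session")
def sim_cache(body, demo_ctrl):
    """Memoized closed-loop runs keyed by (direction, display preset)."""
    cache = {}

    def run(direction: float, display: str, dt: float = 0.002):
        key = (direction, display, dt)
        if key not in cache:
            sc = pf.Scenario(
                body=body, controller=demo_ctrl,
                display=pf.DisplayConfig.preset(display),
                perturbation=pf.PerturbationSpec(direction=direction),
                dt=dt)
            cache[key] = pf.simulate(sc)
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
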