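from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import porevoc as pv

settings.register_profile(
    "porevoc",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("porevoc")


@pytest.fixture(scope="session")
def ag():
    """Reference (AG)6(AG-T115C) fixture."""
    return pv.load_fixture("ag_t115c")


@pytest.fixture(scope="session")
def quiet_pore(ag):
    """The reference pore with all noise sources switched off."""
    return replace(ag.pore, rms_noise=0.0, level_jitter_pct=0.0)


def make_scenario(fixture, concentrations, duration, seed, pore=None):
    return pv.SimulationScenario(
        pore=pore or fixture.pore,
        segments=(pv.Segment(duration, fixture.mixture(concentrations)),),
        seed=seed)


@pytest.fixture(scope="session")
def scenario_factory():
    return make_scenario
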