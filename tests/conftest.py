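import warnings

import pytest
from hypothesis import HealthCheck, settings

from smoltchain import broodtable as bt
from smoltchain import lifecycle_sim as sim
from smoltchain import mechmodels as mm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="overflow encountered")
warnings.filterwarnings(
    "ignore", message="Maximum Likelihood optimization failed")


@pytest.fixture(scope="session")
def sim_output():
    """One default 60-year simulated dataset shared across tests."""
    return sim.simulate(seed=1)


@pytest.fixture(scope="session")
def brood(sim_output):
    return bt.build_brood_table(sim_output.bio)


@pytest.fixture(scope="session")
def ricker(brood):
    return bt.fit_ricker(brood)


@pytest.fixture(scope="session")
def productivity(brood, ricker):
    prod, sas_mig = bt.survival_metrics(brood, ricker)
    return prod, sas_mig


@pytest.fixture(scope="session")
def frames(sim_output, productivity):
    prod, sas_mig = productivity
    return mm.build_frames(sim_output.bio, sim_output.env, prod, sas_mig)
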