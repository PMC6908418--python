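import pytest
from hypothesis import HealthCheck, settings

from cfm_croco.parameters import Parameters
from cfm_croco.simulator import canonical_forcing, run_diel

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return Parameters.default()


@pytest.fixture(scope="session")
def run20():
    """Converged canonical run at the 20% O2 treatment (186 uM, 28 degC)."""
    return run_diel(canonical_forcing(0.20), Parameters.default(), dt=0.02)


@pytest.fixture(scope="session")
def run5():
    """Converged canonical run at the 5% O2 treatment (46 uM, 28 degC)."""
    return run_diel(canonical_forcing(0.05), Parameters.default(), dt=0.02)
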