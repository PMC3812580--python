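import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20130731)


@pytest.fixture
def pilot_fixture(tmp_path):
    """Synthetic pilot-session annotation export (counts match the study)."""
    from sonimotion.behavior import write_pilot_fixture

    path = tmp_path / "pilot.tsv"
    write_pilot_fixture(path)
    return path
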