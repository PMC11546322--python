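import pytest
from hypothesis import settings

from backfill_qol import MonitoringConfig, TrialConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def monitoring():
    """Default monitoring setup: target DLT 25%, theta0 20%, QoL floor -10."""
    return MonitoringConfig()


@pytest.fixture
def trial_config():
    return TrialConfig()
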