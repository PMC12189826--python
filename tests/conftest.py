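import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from psgdetect.synth import SynthConfig, simulate_record


@pytest.fixture(scope="session")
def small_sim():
    """One 5-minute synthetic recording with events of both classes."""
    cfg = SynthConfig(duration_s=300.0, sdb_rate_per_h=30.0, plms_train_rate_per_h=6.0,
                      lm_isolated_rate_per_h=20.0, p_rrlm=0.5, seed=42)
    record, schedule = simulate_record(cfg)
    return cfg, record, schedule


@pytest.fixture
def rng():
    return np.random.default_rng(7)
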