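import numpy as np
import pytest

from eegreduce.synthetic_eeg import GeneratorConfig, generate_record


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_record():
    """A 2-minute 23-channel record with one 30 s seizure."""
    cfg = GeneratorConfig(duration_s=120.0, n_events=1,
                          event_duration_bounds=(25.0, 35.0),
                          seizure_gain=8.0, seed=7)
    return generate_record(cfg, record_id="small")
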