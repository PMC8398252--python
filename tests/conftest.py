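import numpy as np
import pytest

import ecgbeats as eb


@pytest.fixture(scope="session")
def clean_60bpm():
    """60 s noise-free all-normal record at 60 bpm with ground truth."""
    cfg = eb.SynthConfig.clean(
        duration=60.0, mean_hr=60.0, class_mix=(1, 0, 0, 0, 0), seed=3
    )
    return eb.generate(cfg)


@pytest.fixture(scope="session")
def default_synth():
    """60 s record at the default (moderately noisy, mixed-class) settings."""
    return eb.generate(eb.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def emg10db_synth():
    """60 s mixed-class record with EMG noise at 10 dB SNR."""
    return eb.generate(eb.SynthConfig(emg_snr_db=10.0, seed=7))


@pytest.fixture
def fragment_factory():
    """Build a HeartbeatFragment from raw samples with sane RR defaults."""

    def make(hb, rr_pre=0.8, rr_pos=0.8, label=None):
        return eb.HeartbeatFragment(
            hb=np.asarray(hb, dtype=float),
            r_index_in_record=500,
            record_id="fix",
            rr_pre=rr_pre,
            rr_pos=rr_pos,
            aami_class=label,
        )

    return make


@pytest.fixture(scope="session")
def random_fragments():
    rng = np.random.default_rng(42)
    return [rng.standard_normal(151) for _ in range(100)]
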