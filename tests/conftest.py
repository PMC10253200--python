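import numpy as np
import pytest

from eegtfdx.io_signals import MultichannelRecording
from eegtfdx.pipeline import preprocess_cohort
from eegtfdx.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """A fast 2+2-subject cohort configuration used across modules."""
    return SynthConfig(
        n_md=2, n_hc=2, n_channels=3, duration=2.0, condition="R", seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort):
    """Filtered, decimated, per-channel segments of the tiny cohort."""
    return preprocess_cohort(tiny_cohort)


@pytest.fixture()
def random_recording() -> MultichannelRecording:
    rng = np.random.default_rng(42)
    return MultichannelRecording(
        samples=rng.standard_normal((4, 1024)) * 20.0,
        fs=256.0,
        subject_id="S01",
        label="MD",
        condition="A",
    )
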