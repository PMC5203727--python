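import numpy as np
import pytest

from tremorkit import (
    GroupLabel,
    ScheduleConfig,
    SubjectSpec,
    generate_subject,
    preprocess_recording,
    segment,
)

#: short rest gap used throughout the tests — rest samples are never
#: analysed, so a short gap only speeds up simulation
QUICK_SCHEDULE = ScheduleConfig(rest_gap_s=2.0)


@pytest.fixture(scope="session")
def quick_schedule():
    return QUICK_SCHEDULE


@pytest.fixture(scope="session")
def pd_subject():
    """A tremor-dominant subject with all model components active."""
    return SubjectSpec(
        subject_id="pd01",
        group=GroupLabel.S_PD,
        tremor_amplitude=1.0,
        tremor_freq_hz=5.0,
        drift_scale=0.5,
        noise_sd=0.1,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def pd_recording(pd_subject, quick_schedule):
    return generate_subject(pd_subject, quick_schedule)


@pytest.fixture(scope="session")
def pd_triplets(pd_recording):
    return preprocess_recording(pd_recording)


@pytest.fixture(scope="session")
def pd_windows(pd_recording):
    return segment(pd_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
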