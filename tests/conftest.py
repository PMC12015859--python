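import numpy as np
import pytest

from stereoattn import GroundTruth, generate_trial_schedule, standard_montage


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def small_schedule():
    """20 trials: 10 event-free, 5 one-event, 5 two-event."""
    return generate_trial_schedule(20, (10, 5, 5), n_blocks=4, seed=7)


@pytest.fixture(scope="session")
def event_free_schedule():
    return generate_trial_schedule(24, (24, 0, 0), seed=3)


@pytest.fixture(scope="session")
def ground_truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def small_recording(small_schedule, ground_truth, montage):
    from stereoattn import generate_subject

    rec, truth, presses = generate_subject(small_schedule, ground_truth,
                                           montage, seed=42)
    return rec, truth, presses
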