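import numpy as np
import pytest

from burstrf import make_gaussian_noise, simulate_response
from burstrf.synthetic import default_neuron


@pytest.fixture(scope="session")
def stim4x4():
    """Dense Gaussian noise at the study's nominal conditions (short run)."""
    return make_gaussian_noise((4, 4), 4096, frame_duration=0.020,
                               rms_contrast=0.33, seed=2)


@pytest.fixture(scope="session")
def stim4x4_long():
    return make_gaussian_noise((4, 4), 8192, frame_duration=0.020,
                               rms_contrast=0.33, seed=2)


@pytest.fixture(scope="session")
def energy_recording(stim4x4_long):
    """An energy-model (single quadratic subunit) cell and its response."""
    neuron = default_neuron("energy", seed=100)
    record = simulate_response(neuron, stim4x4_long, n_repeats=4, seed=200)
    return neuron, record


@pytest.fixture(scope="session")
def pgn_recording(stim4x4_long):
    """A bursting two-subunit reticular-like cell and its response."""
    neuron = default_neuron("pgn_two_subunit", seed=3)
    record = simulate_response(neuron, stim4x4_long, n_repeats=6, seed=7)
    return neuron, record


def spike_frames_of(record, frame_duration, n_frames, lag):
    f = np.concatenate([np.floor(t / frame_duration).astype(np.int64)
                        for t in record.repeats])
    return f[(f >= lag - 1) & (f < n_frames)]
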