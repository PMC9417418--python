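import numpy as np
import pytest

from sleepod.preproc import EEGRecording, Segment, select_nrem
from sleepod.synthetic import SimulationSpec, generate_nrem_eeg

FS = 500.0


@pytest.fixture(scope="session")
def noisy_recording():
    """Small noisy simulation shared by detector tests (2 ch, 3 min)."""
    spec = SimulationSpec(duration=180, n_channels=2, noise_rms=20.0, seed=101)
    rec, hyp, mask, truth = generate_nrem_eeg(spec)
    segs = select_nrem(rec, hyp, mask)
    return rec, segs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(data, sfreq=FS, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or [f"c{i}" for i in range(data.shape[0])]
    return EEGRecording(data=data, ch_names=names, sfreq=sfreq)


def whole_segment(n_samples, sfreq=FS, stage="N2"):
    return [Segment(0.0, n_samples / sfreq, stage)]
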