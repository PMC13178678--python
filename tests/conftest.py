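import numpy as np
import pytest

from ecgkit.io import ECGRecord, PredictionSet
from ecgkit.synth import BeatTemplate, simulate_clean_ecg


@pytest.fixture
def clean_record() -> ECGRecord:
    """Default 10 s, 250 Hz, 60 bpm clean record."""
    return simulate_clean_ecg(BeatTemplate(), 250.0, 10.0, seed=42, record_id="fix")


def make_tone_record(freq_hz: float, amplitude: float = 1.0, fs: float = 250.0,
                     duration_s: float = 10.0, phase: float = 0.0) -> ECGRecord:
    """12 identical leads carrying one sinusoid."""
    t = np.arange(int(fs * duration_s)) / fs
    tone = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return ECGRecord(f"tone{freq_hz}", np.tile(tone, (12, 1)), fs)


def make_prediction_set(scores, truths, labels=None) -> PredictionSet:
    scores = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    truths = np.atleast_2d(np.asarray(truths).T).T
    if scores.ndim == 1:
        scores = scores[:, None]
        truths = truths[:, None]
    labels = labels or [f"l{j}" for j in range(scores.shape[1])]
    ids = [f"r{i}" for i in range(scores.shape[0])]
    return PredictionSet(ids, labels, scores, truths)
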