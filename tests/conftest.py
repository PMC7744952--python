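import numpy as np
import pytest

from triagesim.waveform import (
    ECGMorphologyParams,
    WaveComponent,
    WaveformRecord,
)


@pytest.fixture
def basic_params():
    """A plain one-beat-per-second morphology with elevated ST."""
    return ECGMorphologyParams(
        heart_rate=60.0,
        p=WaveComponent(0.10, -0.22, 0.02),
        q=WaveComponent(-0.35, -0.03, 0.006),
        r=WaveComponent(1.2, 0.0, 0.009),
        s=WaveComponent(-0.35, 0.03, 0.006),
        t=WaveComponent(0.25, 0.25, 0.025),
        st_offset=0.2,
    )


def spike_train(r_times, duration=10.0, fs=250.0, amp=1.0, width=0.01):
    """Record with Gaussian spikes at given times; ground truth attached."""
    t = np.arange(round(duration * fs)) / fs
    v = np.zeros_like(t)
    for rt in r_times:
        v += amp * np.exp(-((t - rt) ** 2) / (2 * width**2))
    return WaveformRecord(
        record_id="spikes",
        fs=fs,
        duration=duration,
        v=v,
        ground_truth={"r_times": np.asarray(r_times, dtype=float)},
    )


@pytest.fixture
def make_spike_train():
    return spike_train
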