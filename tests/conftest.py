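import math

import numpy as np
import pytest

from eegfbn import ChannelLayout, CouplingEvent, Recording, default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture
def mini_layout():
    """Three channels spread over the three regions."""
    return ChannelLayout(
        labels=("a", "b", "c"),
        region_of={"a": "frontal", "b": "central", "c": "occipital"},
    )


@pytest.fixture
def tone_recording(layout):
    """Every channel a pure 40 Hz tone with a channel-specific phase."""
    fs = 1000.0
    t = np.arange(int(2 * fs)) / fs
    data = np.stack(
        [np.cos(2 * math.pi * 40.0 * t + 0.3 * k) for k in range(layout.n_channels)]
    )
    return Recording(data=data, fs=fs, layout=layout)


def core_pair_events(n_events, start=2.0, spacing=4.8, duration=1.0, lag=math.pi / 2,
                     strength=0.9):
    """Evenly spaced events coupling the screening core pairs."""
    return [
        CouplingEvent(
            start_s=start + k * spacing,
            duration_s=duration,
            channel_pairs=(("Fz", "Cz"), ("Fz", "Pz")),
            phase_lag_rad=lag,
            coupling_strength=strength,
        )
        for k in range(n_events)
    ]
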