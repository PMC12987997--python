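import numpy as np
import pytest

from psgstats.clusterstats import build_graph
from psgstats.preprocess import Hypnogram, Montage, Recording
from psgstats.synth import (generate_hypnogram, generate_recording,
                            synthetic_cap)


@pytest.fixture(scope="session")
def cap64():
    return synthetic_cap(64)


@pytest.fixture(scope="session")
def cap8():
    return synthetic_cap(8)


@pytest.fixture(scope="session")
def eeg_labels64(cap64):
    return [l for l in cap64.labels if not l.startswith("M")]


@pytest.fixture(scope="session")
def graph64(cap64, eeg_labels64):
    return build_graph(cap64, "distance", labels=eeg_labels64)


@pytest.fixture(scope="session")
def short_night():
    """75-min hypnogram with two cycles and no artifacts."""
    return generate_hypnogram(75, cycle_len_min=37.5, seed=3,
                              artifact_frac=0.0)


@pytest.fixture(scope="session")
def small_recording(short_night, cap8):
    """One synthetic night on 8 EEG channels + mastoids, with its injected
    spindle events (session-scoped: waveform synthesis is the slow part)."""
    rec, events = generate_recording(short_night, cap8, seed=11,
                                     theta_gain=1.0, spindle_rate=2.0)
    return rec, events


def stage_hypnogram(pattern: str, artifact=None) -> Hypnogram:
    """Compact hypnogram builder: e.g. 'W,N1,N2*30,N3*20,REM*10'."""
    stages = []
    for tok in pattern.split(","):
        if "*" in tok:
            s, k = tok.split("*")
            stages += [s] * int(k)
        else:
            stages.append(tok)
    art = np.zeros(len(stages), dtype=bool) if artifact is None else artifact
    return Hypnogram(np.array(stages, dtype=object), art)


def flat_recording(n_channels: int, n_samples: int, fs: float = 500.0,
                   value: float = 0.0, labels=None) -> Recording:
    labels = labels or [f"E{i+1:02d}" for i in range(n_channels)]
    types = ["EEG"] * n_channels
    return Recording(np.full((n_channels, n_samples), value, dtype=float),
                     fs, labels, types)
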