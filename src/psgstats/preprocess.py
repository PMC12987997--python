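"""Signal conditioning ahead of spectral analysis.

All operations here are deterministic and order-independent of channel layout:
mastoid re-referencing, zero-phase high-pass filtering, position-weighted
interpolation of bad channels, and stage/artifact-gated segmentation into
overlapping analysis windows.

Conventions: times are seconds, 0-based, half-open intervals ``[start, end)``;
signals are microvolts in ``(n_channels, n_samples)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

STAGES = ("W", "N1", "N2", "N3", "REM")

#: sleep stages whose epochs count as consolidated NREM for spectral analysis
NREM_STAGES = frozenset({"N2", "N3"})


@dataclass
class Recording:
    """Multichannel polysomnography signal block.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (500 in the acquisition setup modelled here).
    labels : list of str
        Unique channel names.
    types : list of str
        Per-channel type, one of ``{"EEG", "EOG", "EMG", "ECG", "mastoid"}``.
    reference : str
        Free-text tag describing the current reference state.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    types: list[str]
    reference: str = "recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/data channel count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.types) != len(self.labels):
            raise ValueError("types/labels length mismatch")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.types) if t == "EEG"], dtype=int
        )

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.labels), list(self.types),
            self.reference,
        )


@dataclass
class Hypnogram:
    """Scored sleep stages in 30-s epochs with per-epoch artifact flags."""

    stages: np.ndarray  # array of str, one of STAGES
    artifact: np.ndarray  # bool, same length
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.stages.shape != self.artifact.shape:
            raise ValueError("stages and artifact must have equal length")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len

    def clean_mask(self, stage_set) -> np.ndarray:
        """Boolean mask of artifact-free epochs whose stage is in *stage_set*."""
        stage_set = set(stage_set)
        in_set = np.array([s in stage_set for s in self.stages], dtype=bool)
        return in_set & ~self.artifact

    def minutes(self, stage_set, artifact_free: bool = True) -> float:
        """Total minutes spent in *stage_set* (artifact-free by default)."""
        if artifact_free:
            mask = self.clean_mask(stage_set)
        else:
            stage_set = set(stage_set)
            mask = np.array([s in stage_set for s in self.stages], dtype=bool)
        return mask.sum() * self.epoch_len / 60.0

    def sample_mask(self, stage_set, fs: float, n_samples: int,
                    artifact_free: bool = True) -> np.ndarray:
        """Per-sample boolean mask for a recording of *n_samples* at *fs*."""
        if artifact_free:
            em = self.clean_mask(stage_set)
        else:
            ss = set(stage_set)
            em = np.array([s in ss for s in self.stages], dtype=bool)
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_len * fs))
        for i in np.flatnonzero(em):
            lo = i * spe
            hi = min((i + 1) * spe, n_samples)
            if lo < n_samples:
                mask[lo:hi] = True
        return mask


@dataclass
class Montage:
    """Electrode positions: channel label -> (x, y, z), consistent units.

    +x is toward the right ear, +y toward the nasion, +z toward the vertex.
    """

    positions: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        self.positions = {
            k: tuple(float(c) for c in v) for k, v in self.positions.items()
        }

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    def coords(self, labels=None) -> np.ndarray:
        labels = self.labels if labels is None else list(labels)
        return np.array([self.positions[l] for l in labels], dtype=float)

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tx\ty\tz\n")
            for lab, (x, y, z) in self.positions.items():
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")

    @classmethod
    def from_table(cls, path) -> "Montage":
        positions = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("label"):
                fh.seek(0)
            for line in fh:
                parts = line.split()
                if len(parts) != 4:
                    continue
                positions[parts[0]] = tuple(map(float, parts[1:]))
        return cls(positions)


@dataclass
class EpochSet:
    """Stage-pure, artifact-free analysis windows cut from one recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    labels: list[str]
    stage_set: frozenset
    epoch_len_s: float = 8.192
    overlap: float = 0.5
    #: start sample of each window in the source recording
    starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2] if self.epochs.size else int(
            round(self.epoch_len_s * self.fs))


def rereference(rec: Recording, refs: tuple[str, str]) -> Recording:
    """Re-reference to the mean of two (mastoid) channels.

    Every channel other than the two references has the sample-wise mean of the
    reference pair subtracted. The reference channels themselves are left
    untouched so the transform can be audited.
    """
    if len(refs) != 2:
        raise ValueError("exactly two reference channels required")
    idx = [rec.index(r) for r in refs]
    ref_mean = rec.data[idx].mean(axis=0)
    out = rec.copy()
    keep = np.ones(rec.n_channels, dtype=bool)
    keep[idx] = False
    out.data[keep] -= ref_mean
    out.reference = f"linked:{refs[0]}+{refs[1]}"
    return out


def highpass(rec: Recording, cutoff: float = 0.1, order: int = 2) -> Recording:
    """Zero-phase high-pass filter (Butterworth, forward-backward).

    The forward-backward application squares the magnitude response, so the
    effective attenuation at the cutoff is 6 dB for the default 2nd-order
    design; DC is removed entirely.
    """
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    return out


def interpolate_bad(rec: Recording, montage: Montage, bad) -> Recording:
    """Replace bad EEG channels by inverse-squared-distance weighted averages.

    Weights are ``1 / d^2`` over all good EEG channels; good channels are
    untouched. Interpolation uses the *input* values of the good channels, so
    the result does not depend on the order of the bad list.
    """
    bad = list(bad)
    if not bad:
        return rec.copy()
    eeg = set(rec.labels[i] for i in rec.eeg_indices())
    unknown = [b for b in bad if b not in eeg]
    if unknown:
        raise ValueError(f"bad channels must be EEG channels, got {unknown}")
    good = [l for l in sorted(eeg, key=rec.index) if l not in bad]
    if len(good) < 2:
        raise ValueError("need at least 2 good EEG channels to interpolate")
    out = rec.copy()
    gpos = montage.coords(good)
    gdat = rec.data[[rec.index(g) for g in good]]
    for b in bad:
        bpos = np.array(montage.positions[b], dtype=float)
        d2 = np.sum((gpos - bpos) ** 2, axis=1)
        if np.any(d2 == 0):
            w = (d2 == 0).astype(float)
        else:
            w = 1.0 / d2
        w = w / w.sum()
        out.data[rec.index(b)] = w @ gdat
    return out


def _clean_runs(hyp: Hypnogram, stage_set) -> list[tuple[int, int]]:
    """Maximal runs of contiguous artifact-free epochs of *stage_set*.

    Returned as half-open epoch-index intervals ``[lo, hi)``.
    """
    mask = hyp.clean_mask(stage_set)
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def segment(rec: Recording, hyp: Hypnogram, stage_set,
            epoch_len_s: float = 8.192, overlap: float = 0.5) -> EpochSet:
    """Cut overlapping stage-pure windows from artifact-free scored sleep.

    Within each maximal contiguous run of artifact-free epochs of *stage_set*,
    windows of *epoch_len_s* are placed from the run start at stride
    ``epoch_len_s * (1 - overlap)`` while they fit entirely inside the run;
    windows never straddle two runs, so every window is stage-pure. An empty
    result is returned (not an error) when no window fits.
    """
    if rec.n_samples + rec.fs * hyp.epoch_len < hyp.duration_s * rec.fs:
        raise ValueError("recording shorter than hypnogram span")
    stage_set = frozenset(stage_set)
    spw = int(round(epoch_len_s * rec.fs))
    stride = epoch_len_s * (1 - overlap) * rec.fs
    if stride <= 0:
        raise ValueError("overlap must be < 1")
    spe = int(round(hyp.epoch_len * rec.fs))
    starts = []
    for lo, hi in _clean_runs(hyp, stage_set):
        run_lo = lo * spe
        run_hi = min(hi * spe, rec.n_samples)
        s = float(run_lo)
        while s + spw <= run_hi:
            starts.append(int(round(s)))
            s += stride
    if not starts:
        return EpochSet(np.empty((0, rec.n_channels, spw)), rec.fs,
                        list(rec.labels), stage_set, epoch_len_s, overlap,
                        np.array([], dtype=int))
    starts = np.array(starts, dtype=int)
    epochs = np.stack([rec.data[:, s:s + spw] for s in starts])
    return EpochSet(epochs, rec.fs, list(rec.labels), stage_set,
                    epoch_len_s, overlap, starts)
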