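"""Discrete sleep-spindle detection and summary metrics.

Spindles are transient 12-16 Hz bursts in N2/N3 sleep. The detector is a
standard amplitude-criterion design: band-pass the signal, form a sliding RMS
envelope, threshold at ``mean + k * SD`` of the envelope over artifact-free
N2/N3 samples of that channel, and keep supra-threshold runs of plausible
duration (events separated by less than a merge gap are joined first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .preprocess import Hypnogram, Recording


@dataclass
class SpindleEvent:
    channel: str
    onset_s: float
    offset_s: float
    peak_env: float  # uV, max band-limited RMS envelope within the event

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SpindleMetrics:
    """Per-night summary: event count, density per minute, mean peak envelope.

    ``envelope`` is the mean over events of the per-event envelope maximum and
    is ``nan`` (missing, not zero) when there are no events.
    """

    count: int
    density: float   # events / minute of artifact-free N2+N3
    envelope: float  # uV


def _rms_envelope(x: np.ndarray, fs: float, win_s: float = 0.2) -> np.ndarray:
    n = max(1, int(round(win_s * fs)))
    return np.sqrt(ndimage.uniform_filter1d(x * x, size=n, mode="nearest"))


def detect_spindles(rec: Recording, hyp: Hypnogram,
                    band: tuple[float, float] = (12.0, 16.0),
                    thresh_sd: float = 1.5,
                    dur: tuple[float, float] = (0.5, 3.0),
                    merge_gap_s: float = 0.1,
                    rms_win_s: float = 0.2,
                    min_n23_s: float = 60.0,
                    channels=None) -> list[SpindleEvent]:
    """Detect spindle events per channel in artifact-free N2/N3 sleep.

    The threshold is channel-specific (envelope mean + *thresh_sd* SD over all
    artifact-free N2/N3 samples of that channel), which absorbs channel-wise
    amplitude differences. Events are clipped to stage runs, so none overlaps
    wake, N1, REM, or an artifact-flagged epoch.
    """
    mask = hyp.sample_mask({"N2", "N3"}, rec.fs, rec.n_samples)
    if mask.sum() < min_n23_s * rec.fs:
        raise ValueError("insufficient artifact-free N2/N3 sleep")
    sos = sps.butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    if channels is None:
        ch_idx = rec.eeg_indices()
    else:
        ch_idx = np.array([rec.index(c) for c in channels], dtype=int)
    gap = int(round(merge_gap_s * rec.fs))
    events: list[SpindleEvent] = []
    # contiguous N2/N3 sample segments; events are detected within segments
    segs = _segments(mask)
    for ci in ch_idx:
        bp = sps.sosfiltfilt(sos, rec.data[ci])
        env = _rms_envelope(bp, rec.fs, rms_win_s)
        mu = env[mask].mean()
        sd = env[mask].std()
        thr = mu + thresh_sd * sd
        for lo, hi in segs:
            e = env[lo:hi]
            above = e > thr
            if not above.any():
                continue
            runs = _runs(above)
            runs = _merge_runs(runs, gap)
            for a, b in runs:
                d = (b - a) / rec.fs
                if dur[0] <= d <= dur[1]:
                    events.append(SpindleEvent(
                        rec.labels[ci], (lo + a) / rec.fs, (lo + b) / rec.fs,
                        float(e[a:b].max())))
    return events


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    return _segments(above)


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if a - pb < gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def spindle_metrics(events: list[SpindleEvent], hyp: Hypnogram) -> SpindleMetrics:
    """Whole-head (or per-channel, if *events* is pre-filtered) summary."""
    minutes = hyp.minutes({"N2", "N3"})
    if minutes <= 0:
        raise ValueError("zero artifact-free N2+N3 minutes: density undefined")
    count = len(events)
    density = count / minutes
    envelope = (float(np.mean([e.peak_env for e in events]))
                if events else float("nan"))
    return SpindleMetrics(count, density, envelope)


def metrics_by_channel(events: list[SpindleEvent], hyp: Hypnogram,
                       labels) -> dict[str, SpindleMetrics]:
    """Per-channel metrics for topographic maps (missing channels get 0/0/nan)."""
    by = {l: [] for l in labels}
    for e in events:
        if e.channel in by:
            by[e.channel].append(e)
    return {l: spindle_metrics(evs, hyp) if True else None
            for l, evs in by.items()}
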