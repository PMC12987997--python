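"""Average power spectra, band summaries, sleep cycles, and the SWA slope.

Spectra are computed per channel from Hann-windowed 8.192-s windows
(4096 samples at 500 Hz, hence a 0.122-Hz grid), converted to power and
averaged across windows. Normalisation is amplitude-correct: the window is
compensated by its coherent gain so a unit-amplitude sinusoid contributes a
window-independent 0.5 uV^2 at its bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet, Hypnogram, Recording, segment

#: canonical analysis bands, Hz (closed intervals on bin centers)
BANDS = {
    "swa": (0.5, 4.0),
    "theta": (4.25, 8.0),
    "spindle": (12.0, 16.0),
}

FMAX = 30.0


@dataclass
class PowerSpectrum:
    freqs: np.ndarray          # Hz, 0 .. 30
    power: np.ndarray          # (n_channels, n_bins), uV^2
    labels: list[str]
    n_epochs: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SleepCycle:
    """One NREM period and its terminating REM period (30-s epoch indices).

    ``[nrem_start, nrem_end)`` is the NREM period, ``[nrem_end, rem_end)``
    spans everything up to and including the terminating REM period.
    """

    nrem_start: int
    nrem_end: int
    rem_end: int

    def __post_init__(self) -> None:
        if not (self.nrem_start < self.nrem_end <= self.rem_end):
            raise ValueError("require nrem_start < nrem_end <= rem_end")


def spectrum(epochs: EpochSet, fmax: float = FMAX) -> PowerSpectrum:
    """Hann-windowed FFT power averaged over windows, reported up to *fmax*.

    Power at bin k is ``2 |X_k|^2 / (sum w)^2`` (one-sided, coherent-gain
    compensated), with no doubling at DC. Bin spacing is ``fs / n_samples``
    (0.1220703125 Hz for 4096 samples at 500 Hz).
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    x = epochs.epochs
    n = x.shape[2]
    w = np.hanning(n)
    cg = w.sum()
    spec = np.fft.rfft(x * w, axis=2)
    p = (np.abs(spec) ** 2) * (2.0 / cg**2)
    p[..., 0] /= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    p = p.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    keep = freqs <= fmax + 1e-12
    return PowerSpectrum(freqs[keep], p[:, keep], list(epochs.labels),
                         epochs.n_epochs)


def band_power(spec: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Per-channel mean power over bins with center frequency in ``[low, high]``.

    The band edges are inclusive on bin centers, so the 4.25-Hz theta edge
    excludes every bin that the 0.5-4 Hz SWA band includes.
    """
    low, high = band
    if low >= high:
        raise ValueError("band low must be < high")
    sel = (spec.freqs >= low - 1e-9) & (spec.freqs <= high + 1e-9)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return spec.power[:, sel].mean(axis=1)


def band_power_from_recording(rec: Recording, hyp: Hypnogram, band, stage_set,
                              epoch_len_s: float = 8.192,
                              overlap: float = 0.5) -> np.ndarray:
    """Convenience composition: segment -> spectrum -> band_power."""
    eps = segment(rec, hyp, stage_set, epoch_len_s, overlap)
    return band_power(spectrum(eps), band)


def detect_cycles(hyp: Hypnogram, min_nrem_min: float = 15.0,
                  min_rem_min: float = 5.0,
                  max_gap_min: float = 5.0) -> list[SleepCycle]:
    """Segment the night into NREM-REM cycles (modified Feinberg rules).

    A NREM period is a run of N2/N3 epochs totalling at least *min_nrem_min*
    minutes, tolerating interruptions by other stages shorter than
    *max_gap_min*. The period ends at the REM period that follows it; REM
    periods must last at least *min_rem_min* minutes, except the first, which
    has no minimum. Returns an empty list when no REM is present.
    """
    stages = hyp.stages
    n = len(stages)
    epm = 60.0 / hyp.epoch_len      # epochs per minute
    min_nrem = int(round(min_nrem_min * epm))
    min_rem = int(round(min_rem_min * epm))
    max_gap = int(round(max_gap_min * epm))

    if not any(s == "REM" for s in stages):
        return []

    cycles: list[SleepCycle] = []
    i = 0
    first_rem_seen = False
    while i < n:
        # find the start of a candidate NREM period
        while i < n and stages[i] not in ("N2", "N3"):
            i += 1
        if i >= n:
            break
        start = i
        nrem_count = 0
        j = i
        last_nrem = i
        while j < n:
            if stages[j] in ("N2", "N3"):
                nrem_count += 1
                last_nrem = j
                j += 1
            elif stages[j] == "REM":
                break
            else:
                # tolerate short N1/W interruptions
                k = j
                while k < n and stages[k] not in ("N2", "N3", "REM"):
                    k += 1
                if k - j >= max_gap or k >= n:
                    break
                j = k
        if nrem_count < min_nrem:
            i = max(j, i + 1)
            continue
        # advance to the next REM run after the NREM period
        r = last_nrem + 1
        while r < n and stages[r] != "REM":
            r += 1
        if r >= n:
            break
        r_end = r
        while r_end < n and stages[r_end] == "REM":
            r_end += 1
        rem_len = r_end - r
        if rem_len < min_rem and first_rem_seen:
            # too short to terminate a cycle; keep scanning from its end
            i = r_end
            continue
        first_rem_seen = True
        cycles.append(SleepCycle(start, last_nrem + 1, r_end))
        i = r_end
    return cycles


def epoch_swa_series(rec: Recording, hyp: Hypnogram, cycle: SleepCycle,
                     band: tuple[float, float] = BANDS["swa"],
                     epoch_len_s: float = 8.192,
                     overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-30-s-epoch SWA for the N2/N3 epochs of one cycle's NREM period.

    Each 30-s epoch contributes the mean band power of the 8.192-s sub-windows
    that fit inside it (6 at 50% overlap). Returns ``(epoch_indices, swa)``
    with ``swa`` of shape (n_epochs, n_channels).
    """
    spe = int(round(hyp.epoch_len * rec.fs))
    spw = int(round(epoch_len_s * rec.fs))
    stride = int(round(epoch_len_s * (1 - overlap) * rec.fs))
    idx, series = [], []
    for e in range(cycle.nrem_start, cycle.nrem_end):
        if hyp.stages[e] not in ("N2", "N3") or hyp.artifact[e]:
            continue
        lo = e * spe
        hi = min((e + 1) * spe, rec.n_samples)
        starts = list(range(lo, hi - spw + 1, stride))
        if not starts:
            continue
        wins = np.stack([rec.data[:, s:s + spw] for s in starts])
        eset = EpochSet(wins, rec.fs, list(rec.labels), frozenset({"N2", "N3"}),
                        epoch_len_s, overlap, np.array(starts))
        series.append(band_power(spectrum(eset), band))
        idx.append(e)
    return np.array(idx, dtype=int), (np.array(series) if series
                                      else np.empty((0, rec.n_channels)))


def ols_slope(y: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Ordinary least-squares slope of *y* against *x* (default 0, 1, 2, ...).

    *y* may be 1-D or (n, channels); returns a scalar or per-channel slopes.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(y.shape[0], dtype=float) if x is None else np.asarray(
        x, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 points for a slope")
    xc = x - x.mean()
    return xc @ (y - y.mean(axis=0)) / (xc @ xc)


def swa_slope_first_cycle(rec: Recording, hyp: Hypnogram,
                          band: tuple[float, float] = BANDS["swa"]) -> np.ndarray:
    """OLS slope of per-epoch SWA against epoch index over the first cycle.

    Units: uV^2 per 30-s epoch, per channel. Requires at least 3 qualifying
    N2/N3 epochs in the first cycle's NREM period.
    """
    cycles = detect_cycles(hyp)
    if not cycles:
        raise ValueError("no sleep cycle found in hypnogram")
    idx, swa = epoch_swa_series(rec, hyp, cycles[0], band)
    if len(idx) < 3:
        raise ValueError("fewer than 3 qualifying epochs in first cycle")
    return ols_slope(swa, idx)
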