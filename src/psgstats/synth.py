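"""Synthetic within-subject trauma/neutral study datasets with known truth.

Everything downstream (preprocessing, spectra, spindle detection, cluster
inference, behavioural scoring) is exercised against data from this module,
so every generator records exactly what it planted:

* hypnograms from a cycle-scaffolded semi-Markov bout model (alternating
  NREM -> REM cycles, N3 mass declining across the night),
* EEG as 1/f^chi background plus stage-gated oscillations (slow activity in
  consolidated NREM with a within-cycle power slope and a per-cycle decay,
  REM theta scaled by a per-subject/condition gain, Poisson spindle bursts
  with raised-cosine envelopes in artifact-free N2/N3),
* film-period heart beats with a trauma-window rate elevation,
* behavioural outcomes (six-day intrusion diary counts, provocation-task
  negative-affect change) tied to the planted sleep effects through a
  Gaussian copula with tie-aware Spearman calibration, so the target rank
  correlation is hit in expectation even on discrete counts.

Cohorts can be generated in two signal modes: ``"eeg"`` synthesises full
waveforms (used to validate the measurement chain end-to-end), while
``"maps"`` draws the per-channel band-power and spindle-metric maps directly
from the same generative parameters, which makes many-seed statistical
simulations affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .preprocess import Hypnogram, Montage, Recording
from .spindles import SpindleEvent

FS = 500.0
FILM_DURATION_MIN = 12
HR_WINDOW = (7, 9)        # 1-based film minutes
SLEEP_MEASURES = ("swa", "rem_theta", "spindle_count", "spindle_envelope")
OUTCOMES = ("intrusions", "affect", "hr")

_EPOCH_WIN_S = 8.192      # analysis-window length the maps emulate


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def synthetic_cap(n: int = 64, radius: float = 10.0) -> Montage:
    """Even electrode coverage of the upper scalp via a sunflower spiral,
    plus two mastoids (M1 left, M2 right). Units are centimetres-ish."""
    golden = math.pi * (3 - math.sqrt(5))
    positions = {}
    zmin, zmax = 0.15, 0.99
    for i in range(n):
        z = zmin + (zmax - zmin) * (i + 0.5) / n
        r = math.sqrt(max(0.0, 1 - z * z))
        phi = i * golden
        positions[f"E{i + 1:02d}"] = (radius * r * math.cos(phi),
                                      radius * r * math.sin(phi),
                                      radius * z)
    positions["M1"] = (-0.98 * radius, -0.10 * radius, -0.15 * radius)
    positions["M2"] = (0.98 * radius, -0.10 * radius, -0.15 * radius)
    return Montage(positions)


def patch_near(montage: Montage, point, k: int, labels=None) -> list[str]:
    """The *k* channels closest to *point* — a contiguous scalp patch."""
    labels = [l for l in (labels or montage.labels)
              if not l.upper().startswith("M")]
    pos = montage.coords(labels)
    d = np.linalg.norm(pos - np.asarray(point, dtype=float), axis=1)
    order = np.argsort(d)[:k]
    return [labels[i] for i in order]


def frontal_patch(montage: Montage, k: int = 12) -> list[str]:
    """A frontal-temporal patch: the k channels with the most anterior
    positions (largest y)."""
    labels = [l for l in montage.labels if not l.upper().startswith("M")]
    pos = montage.coords(labels)
    order = np.argsort(-pos[:, 1])[:k]
    return [labels[i] for i in order]


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

DEFAULT_STAGE_PROFILE = {"N2": 0.56, "N3": 0.14, "REM": 0.21}


def _allocate(total: int, weights) -> np.ndarray:
    """Integer allocation of *total* proportional to *weights*
    (largest-remainder rounding)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        out = np.zeros(len(w), dtype=int)
        out[0] = total
        return out
    raw = total * w / w.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - out))
    for i in range(rem):
        out[order[i % len(w)]] += 1
    return out


def generate_hypnogram(total_sleep_min: float = 474.0,
                       stage_profile: dict | None = None,
                       cycle_len_min: float = 90.0,
                       seed: int = 0,
                       n3_decay: float = 0.55,
                       artifact_frac: float = 0.02) -> Hypnogram:
    """Cycle-scaffolded hypnogram with target stage proportions.

    The night is divided into ``round(total / cycle_len)`` cycles; within each
    cycle N2/N3 bouts are laid out and terminated by a REM bout whose share
    grows across the night, while N3 mass decays geometrically (*n3_decay*
    per cycle). Short W/N1 interruptions are sprinkled into the NREM blocks.
    Realised proportions land within a couple of percentage points of the
    targets for nights of a few hundred minutes.
    """
    if total_sleep_min <= 0:
        raise ValueError("total_sleep_min must be positive")
    profile = dict(DEFAULT_STAGE_PROFILE if stage_profile is None
                   else stage_profile)
    if any(v < 0 for v in profile.values()) or sum(profile.values()) > 1 + 1e-9:
        raise ValueError("stage proportions must be nonnegative and sum <= 1")
    rng = np.random.default_rng(seed)
    n_epochs = int(round(total_sleep_min * 2))
    n_cycles = max(1, int(round(total_sleep_min / cycle_len_min)))

    rem_total = int(round(profile.get("REM", 0.0) * n_epochs))
    n3_total = int(round(profile.get("N3", 0.0) * n_epochs))
    rest = n_epochs - rem_total - n3_total - int(
        round(profile.get("N2", 0.0) * n_epochs))
    n1_total = int(round(0.45 * rest))
    w_total = max(0, rest - n1_total)
    n2_total = n_epochs - rem_total - n3_total - n1_total - w_total

    jitter = rng.uniform(0.9, 1.1, size=n_cycles)
    rem_c = _allocate(rem_total, np.arange(1, n_cycles + 1) * jitter)
    n3_c = _allocate(n3_total, n3_decay ** np.arange(n_cycles)
                     * rng.uniform(0.9, 1.1, size=n_cycles))
    n2_c = _allocate(n2_total, jitter[::-1])
    n1_c = _allocate(n1_total, np.ones(n_cycles))
    w_c = _allocate(w_total, np.ones(n_cycles))

    seq: list[str] = []
    for c in range(n_cycles):
        n1, w = n1_c[c], w_c[c]
        if c == 0:
            onset_w = min(w, 2)
            onset_n1 = min(n1, 3)
            seq += ["W"] * onset_w + ["N1"] * onset_n1
            n1 -= onset_n1
            w -= onset_w
        n2a = int(round(0.45 * n2_c[c]))
        block = ["N2"] * n2a + ["N3"] * int(n3_c[c]) + ["N2"] * (n2_c[c] - n2a)
        # sprinkle brief interruptions (bouts of 1-3 epochs, < 5 min each)
        pool = ["N1"] * int(n1) + ["W"] * int(w)
        rng.shuffle(pool)
        while pool and len(block) > 2:
            bout, pool = pool[:rng.integers(1, 4)], pool[rng.integers(1, 4):]
            pos = int(rng.integers(1, len(block)))
            block = block[:pos] + bout + block[pos:]
        seq += block + ["REM"] * int(rem_c[c])
    seq = seq[:n_epochs] + ["N2"] * max(0, n_epochs - len(seq))
    artifact = rng.random(n_epochs) < artifact_frac
    return Hypnogram(np.array(seq, dtype=object), artifact)


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

@dataclass
class RecordingParams:
    """Waveform-synthesis parameters (amplitudes in uV, powers in uV^2).

    Band powers are stated as band-mean bin power in the analysis convention
    (coherent-gain-compensated Hann periodogram, 0.122-Hz grid), so the
    spectral pipeline recovers them directly.
    """

    fs: float = FS
    chi: float = 1.3                   # 1/f^chi background exponent
    background_rms: float = 10.0       # uV
    background_knee_hz: float = 0.5
    swa_base_power: float = 18.0       # band-mean uV^2 at cycle-1 period start
    swa_within_slope: float = 3.0      # uV^2 per 30-s epoch within a cycle
    swa_cycle_decay: float = 0.7       # multiplicative per-cycle amplitude decay
    swa_freq_bin: int = 10             # 10 * 0.1220703125 ~ 1.22 Hz
    theta_power: float = 0.6           # band-mean uV^2 in REM at gain 1
    theta_freq_bin: int = 50           # ~6.10 Hz
    spindle_snr: float = 3.0           # event peak envelope / background envelope
    spindle_dur: tuple = (0.5, 2.0)    # s
    spindle_band: tuple = (12.0, 16.0)
    spindle_ramp_s: float = 0.1        # raised-cosine ramp at each event edge
    mastoid_rms: float = 1.0


def _band_bin_count(band: tuple[float, float], fs: float = FS,
                    nfft: int = 4096) -> int:
    df = fs / nfft
    return int(np.floor(band[1] / df + 1e-9) - np.ceil(band[0] / df - 1e-9)) + 1


def _pink_noise(n: int, fs: float, chi: float, knee: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """1/f^chi noise (flat below *knee*), unit RMS; returns (signal, rfft freqs
    shaping) so callers can read off realised in-band variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = (np.maximum(f[nz], knee)) ** (-chi / 2)
    shape[0] = 0.0
    spec *= shape
    x = np.fft.irfft(spec, n=n)
    x /= x.std()
    return x, (f, shape)


def _band_rms_fraction(f: np.ndarray, shape: np.ndarray,
                       band: tuple[float, float]) -> float:
    """RMS fraction of the shaped-noise variance inside *band*."""
    p = shape**2
    tot = p.sum()
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.sqrt(p[sel].sum() / tot))


def _amp_for_band_mean(power: float, band: tuple[float, float],
                       fs: float = FS) -> float:
    """Sinusoid amplitude whose Hann-windowed band-mean bin power is *power*.

    An on-grid sinusoid of amplitude A concentrates 0.75 A^2 over its three
    central bins in the coherent-gain-compensated convention.
    """
    nb = _band_bin_count(band, fs)
    return math.sqrt(max(power, 0.0) * nb / 0.75)


def generate_recording(hyp: Hypnogram, montage: Montage,
                       subject: str = "s01", condition: str = "neutral",
                       seed: int = 0, params: RecordingParams | None = None,
                       theta_gain: float = 1.0, spindle_rate: float = 4.9,
                       spindle_amp_gain: float = 1.0,
                       swa_within_slope: float | None = None,
                       theta_patch=None) -> tuple[Recording, list[SpindleEvent]]:
    """Synthesise one night of EEG for one subject and condition.

    Returns the recording (all montage channels; mastoids carry only faint
    noise) and the exact list of injected spindle events. *theta_gain*
    multiplies the REM theta amplitude on *theta_patch* channels (all EEG
    channels when None); *spindle_rate* is events per minute of artifact-free
    N2/N3 per channel.
    """
    p = params or RecordingParams()
    if spindle_rate < 0:
        raise ValueError("spindle_rate must be >= 0")
    fs = p.fs
    n = int(round(hyp.duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ev_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    labels = montage.labels
    types = ["mastoid" if l.upper().startswith("M") else "EEG" for l in labels]
    eeg_labels = [l for l, t in zip(labels, types) if t == "EEG"]
    theta_patch = set(theta_patch) if theta_patch is not None else set(eeg_labels)
    slope = p.swa_within_slope if swa_within_slope is None else swa_within_slope

    cycles = _cycle_index(hyp)
    t = np.arange(n) / fs
    df = fs / 4096
    swa_f = p.swa_freq_bin * df
    theta_f = p.theta_freq_bin * df

    # per-epoch gates
    spe = int(round(hyp.epoch_len * fs))
    swa_amp_epoch = np.zeros(hyp.n_epochs)
    nrem_j = _within_period_index(hyp, cycles)
    for e in range(hyp.n_epochs):
        if hyp.stages[e] in ("N2", "N3") and cycles[e] >= 0:
            power = max(0.0, p.swa_base_power + slope * nrem_j[e])
            swa_amp_epoch[e] = (_amp_for_band_mean(power, (0.5, 4.0), fs)
                                * p.swa_cycle_decay ** cycles[e])
    rem_epoch = np.array([s == "REM" for s in hyp.stages])

    theta_amp_base = _amp_for_band_mean(p.theta_power, (4.25, 8.0), fs)

    clean_n23 = hyp.sample_mask({"N2", "N3"}, fs, n)
    minutes_n23 = clean_n23.sum() / fs / 60.0

    data = np.zeros((len(labels), n))
    events: list[SpindleEvent] = []
    for ci, (lab, typ) in enumerate(zip(labels, types)):
        if typ == "mastoid":
            data[ci] = p.mastoid_rms * rng.standard_normal(n)
            continue
        bg, (f_grid, shape) = _pink_noise(n, fs, p.chi, p.background_knee_hz,
                                          rng)
        x = p.background_rms * bg
        # slow activity: global oscillator, per-epoch amplitude gate
        amp_sw = np.repeat(swa_amp_epoch, spe)[:n]
        if amp_sw.any():
            x = x + amp_sw * np.sin(2 * np.pi * swa_f * t
                                    + rng.uniform(0, 2 * np.pi))
        # REM theta
        gain = theta_gain if lab in theta_patch else 1.0
        amp_th = theta_amp_base * gain * np.repeat(
            rem_epoch.astype(float), spe)[:n]
        if amp_th.any():
            x = x + amp_th * np.sin(2 * np.pi * theta_f * t
                                    + rng.uniform(0, 2 * np.pi))
        # spindle bursts
        sigma_band = p.background_rms * _band_rms_fraction(
            f_grid, shape, p.spindle_band)
        amp_spindle = (p.spindle_snr * math.sqrt(2) * sigma_band
                       * spindle_amp_gain)
        for onset, dur, amp, carrier in _draw_spindles(
                clean_n23, fs, spindle_rate, minutes_n23, p.spindle_dur,
                p.spindle_band, amp_spindle, ev_rng):
            i0 = int(round(onset * fs))
            m = int(round(dur * fs))
            tau = np.arange(m) / fs
            # flat-top envelope with raised-cosine ramps at the edges
            ramp = min(p.spindle_ramp_s, dur / 2)
            nr = int(round(ramp * fs))
            env = np.ones(m)
            if nr > 0:
                up = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
                env[:nr] = up
                env[m - nr:] = up[::-1]
            x[i0:i0 + m] += amp * env * np.sin(
                2 * np.pi * carrier * tau + ev_rng.uniform(0, 2 * np.pi))
            events.append(SpindleEvent(lab, onset, onset + dur, amp))
        data[ci] = x
    rec = Recording(data, fs, list(labels), types,
                    reference=f"synthetic:{subject}:{condition}")
    return rec, events


def _draw_spindles(mask: np.ndarray, fs: float, rate: float, minutes: float,
                   dur_range, band, amp, rng) -> list[tuple]:
    """Poisson spindle placements fully inside artifact-free N2/N3 segments."""
    if rate <= 0 or minutes <= 0:
        return []
    from .spindles import _segments
    segs = _segments(mask)
    if not segs:
        return []
    n_ev = rng.poisson(rate * minutes)
    lens = np.array([hi - lo for lo, hi in segs], dtype=float)
    out = []
    for _ in range(n_ev):
        dur = rng.uniform(*dur_range)
        m = int(round(dur * fs))
        avail = lens - m
        ok = avail > 0
        if not ok.any():
            continue
        wsel = np.where(ok, avail, 0.0)
        si = rng.choice(len(segs), p=wsel / wsel.sum())
        lo, hi = segs[si]
        start = int(rng.integers(lo, hi - m))
        carrier = rng.uniform(*band)
        out.append((start / fs, dur, amp, carrier))
    return sorted(out)


def _cycle_index(hyp: Hypnogram) -> np.ndarray:
    """Cycle number per epoch (-1 outside any cycle)."""
    from .spectra import detect_cycles
    out = np.full(hyp.n_epochs, -1, dtype=int)
    for k, cyc in enumerate(detect_cycles(hyp)):
        out[cyc.nrem_start:cyc.rem_end] = k
    return out


def _within_period_index(hyp: Hypnogram, cycles: np.ndarray) -> np.ndarray:
    """Running N2/N3 epoch index within each cycle's NREM period."""
    out = np.zeros(hyp.n_epochs, dtype=int)
    for c in np.unique(cycles):
        if c < 0:
            continue
        j = 0
        for e in np.flatnonzero(cycles == c):
            if hyp.stages[e] in ("N2", "N3"):
                out[e] = j
                j += 1
    return out


# ---------------------------------------------------------------------------
# heart beats
# ---------------------------------------------------------------------------

def generate_beats(condition: str, duration_min: float = FILM_DURATION_MIN,
                   base_bpm: float = 70.0, reactivity: float = 12.0,
                   window: tuple[int, int] = HR_WINDOW, seed: int = 0,
                   jitter: float = 0.03) -> np.ndarray:
    """Beat timestamps (s) for one film viewing.

    Inter-beat intervals are jittered around ``60 / bpm``; in the trauma
    condition the rate is elevated by *reactivity* bpm inside *window*
    (1-based minutes, inclusive) and unchanged elsewhere.
    """
    if base_bpm <= 0:
        raise ValueError("base_bpm must be positive")
    rng = np.random.default_rng(seed)
    lo_s, hi_s = (window[0] - 1) * 60.0, window[1] * 60.0
    end = duration_min * 60.0
    if condition == "trauma" and reactivity != 0:
        segments = [(0.0, lo_s, base_bpm), (lo_s, hi_s, base_bpm + reactivity),
                    (hi_s, end, base_bpm)]
    else:
        segments = [(0.0, end, base_bpm)]
    beats = [float(rng.uniform(0, 0.5))]
    for seg_start, seg_end, bpm in segments:
        rr_mean = 60.0 / bpm
        t = beats[-1]
        while True:
            n_draw = int((seg_end - t) / rr_mean * 1.2) + 16
            rr = np.maximum(rr_mean * (1 + jitter
                                       * rng.standard_normal(n_draw)), 0.2)
            ts = t + np.cumsum(rr)
            inside = ts[ts < seg_end]
            beats.extend(inside.tolist())
            if inside.size < n_draw:    # crossed the segment boundary
                break
            t = ts[-1]
    return np.array([b for b in beats if b < end])


# ---------------------------------------------------------------------------
# copula calibration
# ---------------------------------------------------------------------------

def gaussian_r_for_spearman(rho_s: float) -> float:
    """Latent Pearson correlation giving grade correlation *rho_s* between two
    continuous Gaussians."""
    return 2 * math.sin(math.pi * rho_s / 6)


@lru_cache(maxsize=128)
def _poisson_grades(lam: float, tol: float = 1e-12):
    kmax = int(stats.poisson.ppf(1 - tol, lam)) + 1
    ks = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(ks, lam)
    cdf = np.cumsum(pmf)
    cdf_prev = np.concatenate([[0.0], cdf[:-1]])
    grades = (cdf + cdf_prev) / 2
    var = float(np.sum(pmf * (grades - 0.5) ** 2))
    return ks, pmf, cdf, cdf_prev, grades, var


def spearman_of_gaussian_poisson(r: float, lam: float) -> float:
    """Population Spearman (mid-rank convention) between a standard-normal
    latent and a Poisson(lam) count produced from a Gaussian copula with
    latent correlation *r*."""
    ks, pmf, cdf, cdf_prev, grades, var_y = _poisson_grades(lam)
    scale = r / math.sqrt(2 - r * r) if abs(r) < 1 else math.copysign(1e9, r)
    total = 0.0
    for k in range(len(ks)):
        a = stats.norm.ppf(cdf_prev[k]) if cdf_prev[k] > 0 else -np.inf
        b = stats.norm.ppf(cdf[k]) if cdf[k] < 1 else np.inf
        if not (b > a):
            continue
        val, _ = integrate.quad(
            lambda w: stats.norm.cdf(scale * w) * stats.norm.pdf(w), a, b,
            limit=100)
        total += grades[k] * val
    cov = total - 0.25
    return cov / math.sqrt((1.0 / 12.0) * var_y)


@lru_cache(maxsize=128)
def gaussian_r_for_spearman_poisson(rho_s: float, lam: float) -> float:
    """Invert the tie-aware Spearman map: latent Gaussian correlation whose
    discretised Poisson copula attains Spearman *rho_s*."""
    if rho_s == 0:
        return 0.0
    f = lambda r: spearman_of_gaussian_poisson(r, lam) - rho_s
    lo, hi = (0.0, 0.999999) if rho_s > 0 else (-0.999999, 0.0)
    if f(lo) * f(hi) > 0:
        raise ValueError(f"target Spearman {rho_s} unattainable with "
                         f"Poisson({lam}) marginal")
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class PlantedAssociation:
    """One planted brain-behaviour link: Spearman *rho* between a subject's
    sleep-measure change latent and an outcome, restricted to *channels*
    (None = all EEG channels)."""

    name: str
    measure: str          # one of SLEEP_MEASURES
    outcome: str          # one of OUTCOMES
    rho: float
    channels: tuple | None = None

    def __post_init__(self) -> None:
        if self.measure not in SLEEP_MEASURES:
            raise ValueError(f"unknown sleep measure {self.measure!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the modelled study: 22 subjects, a 64-channel cap,
    ~474 min nights, intrusion counts with mean ~2.24 over six days, and the
    four reported brain-behaviour associations as planted targets.
    """

    n_subjects: int = 22
    n_channels: int = 64
    signal_mode: str = "maps"                 # "maps" | "eeg"
    total_sleep_min: float = 474.0
    cycle_len_min: float = 90.0
    seed_offset: int = 0
    target_assoc: tuple = None                # filled in __post_init__
    # subject-effect scales (log-scale SDs of trauma/neutral ratios)
    theta_gain_mu: float = 0.03
    theta_gain_sigma: float = 0.25
    spindle_rate_base: float = 4.9            # events/min/channel
    spindle_rate_sigma: float = 0.20
    spindle_env_sigma: float = 0.15
    swa_sigma: float = 0.20
    # heart rate
    base_bpm: float = 70.0
    hr_reactivity_mean: float = 12.0
    hr_reactivity_sd: float = 4.0
    # behaviour
    intrusion_lambda: float = 2.24
    affect_pre_mean: float = 14.0
    affect_pre_sd: float = 2.5
    affect_change_mean: float = 4.0
    affect_change_sd: float = 3.0
    # maps-mode measurement model
    map_noise_sigma: float = 0.10             # log-scale multiplicative noise
    theta_background_frac: float = 0.25       # non-oscillatory share of theta band
    recording: RecordingParams = field(default_factory=RecordingParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("need at least 5 subjects")
        if self.signal_mode not in ("maps", "eeg"):
            raise ValueError("signal_mode must be 'maps' or 'eeg'")
        if self.target_assoc is None:
            self.target_assoc = default_associations()
        self.target_assoc = tuple(self.target_assoc)


def default_associations() -> tuple:
    """The modelled study's four directional brain-behaviour hypotheses."""
    return (
        PlantedAssociation("theta-intrusions", "rem_theta", "intrusions",
                           -0.62, None),
        PlantedAssociation("theta-affect", "rem_theta", "affect", -0.551,
                           None),
        PlantedAssociation("spindles-intrusions", "spindle_count",
                           "intrusions", -0.59, None),
        PlantedAssociation("hr-spindle-envelope", "spindle_envelope", "hr",
                           0.556, None),
    )


@dataclass
class GroundTruth:
    """Everything the generators planted, keyed for later recovery checks."""

    seed: int
    injected_spindles: list = field(default_factory=list)
    theta_gain: dict = field(default_factory=dict)      # (subject, cond) -> x
    spindle_rate: dict = field(default_factory=dict)    # (subject, cond) -> /min
    hr_reactivity: dict = field(default_factory=dict)   # subject -> bpm
    latents: dict = field(default_factory=dict)         # measure -> {subject: z}
    intrusions: dict = field(default_factory=dict)      # subject -> count
    affect_change: dict = field(default_factory=dict)   # subject -> points
    target_assoc: tuple = ()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "injected_spindles": [
                {"subject": s, "condition": c, "channel": ch,
                 "onset_s": o, "duration_s": d, "amplitude_uV": a}
                for (s, c, ch, o, d, a) in self.injected_spindles],
            "theta_gain": {f"{s}:{c}": v for (s, c), v in
                           self.theta_gain.items()},
            "spindle_rate": {f"{s}:{c}": v for (s, c), v in
                             self.spindle_rate.items()},
            "hr_reactivity": dict(self.hr_reactivity),
            "latents": {m: dict(v) for m, v in self.latents.items()},
            "intrusions": dict(self.intrusions),
            "affect_change": dict(self.affect_change),
            "target_assoc": [
                {"name": a.name, "measure": a.measure, "outcome": a.outcome,
                 "rho": a.rho,
                 "channels": list(a.channels) if a.channels else None}
                for a in self.target_assoc],
        }


@dataclass
class Cohort:
    """One synthetic study: per-subject sleep maps (or recordings), film-period
    heart beats, diary and affect tables, and the ground truth."""

    config: CohortConfig
    montage: Montage
    subjects: list[str]
    truth: GroundTruth
    maps: dict            # measure -> condition -> (n_subj, n_ch) array
    eeg_labels: list[str]
    beats: dict           # subject -> condition -> timestamps
    diary: pd.DataFrame
    affect: pd.DataFrame  # subject, time (pre|post), na_sum
    sam: pd.DataFrame = None   # subject, condition, time, mood, arousal
    recordings: dict = field(default_factory=dict)   # eeg mode only
    hypnograms: dict = field(default_factory=dict)

    def change_map(self, measure: str) -> np.ndarray:
        """Trauma-minus-neutral subject x channel change scores."""
        return self.maps[measure]["trauma"] - self.maps[measure]["neutral"]

    def outcome_vector(self, outcome: str) -> np.ndarray:
        """Per-subject behavioural outcome, scored from the generated tables
        (diary filtering, PANAS post-minus-pre, or HR peak-window change)."""
        from .behavior import (affect_change, hr_window_mean, intrusion_total,
                               minute_hr)
        if outcome == "intrusions":
            return np.array([intrusion_total(self.diary, s)
                             for s in self.subjects], dtype=float)
        if outcome == "affect":
            out = []
            for s in self.subjects:
                sub = self.affect[self.affect["subject"] == s]
                pre = float(sub.loc[sub["time"] == "pre", "na_sum"].iloc[0])
                post = float(sub.loc[sub["time"] == "post", "na_sum"].iloc[0])
                out.append(affect_change(pre, post))
            return np.array(out)
        if outcome == "hr":
            out = []
            for s in self.subjects:
                vals = {}
                for cond in ("trauma", "neutral"):
                    hr = minute_hr(self.beats[s][cond], FILM_DURATION_MIN)
                    vals[cond] = hr_window_mean(hr, HR_WINDOW)
                out.append(vals["trauma"] - vals["neutral"])
            return np.array(out)
        raise ValueError(f"unknown outcome {outcome!r}")


def generate_cohort(n_subjects: int | None = None,
                    config: CohortConfig | None = None,
                    seed: int = 0) -> Cohort:
    """Generate a full two-condition study with recorded ground truth.

    Outcome variables are tied to the per-subject sleep-effect latents via a
    Gaussian copula whose latent correlations are calibrated so the *rank*
    correlation with each planted target equals the requested rho in
    expectation — tie-aware for discretised counts. Identical seeds yield
    bit-identical cohorts.
    """
    cfg = config or CohortConfig()
    if n_subjects is not None:
        cfg = replace_cfg(cfg, n_subjects=n_subjects)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    subjects = [f"s{i + 1:02d}" for i in range(cfg.n_subjects)]
    montage = synthetic_cap(cfg.n_channels)
    eeg_labels = [l for l in montage.labels if not l.upper().startswith("M")]
    n, nch = cfg.n_subjects, len(eeg_labels)

    truth = GroundTruth(seed=seed, target_assoc=cfg.target_assoc)

    # 1. independent latents per sleep measure
    L = {m: rng.standard_normal(n) for m in SLEEP_MEASURES}
    for m in SLEEP_MEASURES:
        truth.latents[m] = {s: float(z) for s, z in zip(subjects, L[m])}

    # 2. outcome latents from the copula
    by_outcome: dict[str, list[PlantedAssociation]] = {}
    for a in cfg.target_assoc:
        by_outcome.setdefault(a.outcome, []).append(a)
    W: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        assocs = by_outcome.get(outcome, [])
        rs = []
        for a in assocs:
            if outcome == "intrusions":
                rs.append(gaussian_r_for_spearman_poisson(
                    a.rho, cfg.intrusion_lambda))
            else:
                rs.append(gaussian_r_for_spearman(a.rho))
        ss = sum(r * r for r in rs)
        if ss >= 1:
            raise ValueError("planted associations for one outcome are "
                             "jointly infeasible (sum of squared latent "
                             "correlations >= 1)")
        w = math.sqrt(1 - ss) * rng.standard_normal(n)
        for a, r in zip(assocs, rs):
            w = w + r * L[a.measure]
        W[outcome] = w

    # 3. per-subject physiological parameters
    theta_gain = {}
    spindle_rate = {}
    env_gain = {}
    swa_slope = {}
    for i, s in enumerate(subjects):
        theta_gain[(s, "neutral")] = 1.0
        theta_gain[(s, "trauma")] = float(np.exp(
            cfg.theta_gain_mu + cfg.theta_gain_sigma * L["rem_theta"][i]))
        base_rate = cfg.spindle_rate_base * float(
            np.exp(0.1 * rng.standard_normal()))
        spindle_rate[(s, "neutral")] = base_rate
        spindle_rate[(s, "trauma")] = base_rate * float(np.exp(
            cfg.spindle_rate_sigma * L["spindle_count"][i]))
        env_gain[(s, "neutral")] = 1.0
        env_gain[(s, "trauma")] = float(np.exp(
            cfg.spindle_env_sigma * L["spindle_envelope"][i]))
        base_slope = cfg.recording.swa_within_slope
        swa_slope[(s, "neutral")] = base_slope
        swa_slope[(s, "trauma")] = base_slope * float(np.exp(
            math.log(2.36 / 3.00) + cfg.swa_sigma * L["swa"][i]))
    truth.theta_gain = theta_gain
    truth.spindle_rate = spindle_rate

    hr_react = np.maximum(
        0.0, cfg.hr_reactivity_mean + cfg.hr_reactivity_sd * W["hr"])
    truth.hr_reactivity = {s: float(r) for s, r in zip(subjects, hr_react)}

    # 4. behavioural outcomes
    counts = stats.poisson.ppf(stats.norm.cdf(W["intrusions"]),
                               cfg.intrusion_lambda).astype(int)
    truth.intrusions = {s: int(c) for s, c in zip(subjects, counts)}
    aff_change = cfg.affect_change_mean + cfg.affect_change_sd * W["affect"]
    truth.affect_change = {s: float(a) for s, a in zip(subjects, aff_change)}

    diary = _make_diary(subjects, counts, rng)
    affect = _make_affect(subjects, aff_change, cfg, rng)
    sam = _make_sam(subjects, rng)

    beats = {}
    for i, s in enumerate(subjects):
        beats[s] = {
            "neutral": generate_beats(
                "neutral", base_bpm=cfg.base_bpm, reactivity=0.0,
                seed=int(rng.integers(2**31))),
            "trauma": generate_beats(
                "trauma", base_bpm=cfg.base_bpm,
                reactivity=float(hr_react[i]), seed=int(rng.integers(2**31))),
        }

    # 5. sleep measures: channel maps (and waveforms in eeg mode)
    patches = {a.measure: (set(a.channels) if a.channels else None)
               for a in cfg.target_assoc}
    maps = {m: {} for m in SLEEP_MEASURES}
    recordings: dict = {}
    hypnograms: dict = {}
    if cfg.signal_mode == "maps":
        maps = _maps_from_model(cfg, subjects, eeg_labels, theta_gain,
                                spindle_rate, env_gain, swa_slope, patches,
                                rng)
    else:
        for m in SLEEP_MEASURES:
            maps[m] = {c: np.zeros((n, nch)) for c in ("trauma", "neutral")}
        for i, s in enumerate(subjects):
            hyp = generate_hypnogram(cfg.total_sleep_min,
                                     cycle_len_min=cfg.cycle_len_min,
                                     seed=int(rng.integers(2**31)))
            hypnograms[s] = hyp
            for cond in ("trauma", "neutral"):
                rec, events = generate_recording(
                    hyp, montage, s, cond, seed=int(rng.integers(2**31)),
                    params=cfg.recording,
                    theta_gain=theta_gain[(s, cond)],
                    spindle_rate=spindle_rate[(s, cond)],
                    spindle_amp_gain=env_gain[(s, cond)],
                    swa_within_slope=swa_slope[(s, cond)],
                    theta_patch=patches.get("rem_theta"))
                recordings[(s, cond)] = rec
                truth.injected_spindles += [
                    (s, cond, e.channel, e.onset_s, e.duration_s, e.peak_env)
                    for e in events]
    return Cohort(cfg, montage, subjects, truth, maps, eeg_labels, beats,
                  diary, affect, sam=sam, recordings=recordings,
                  hypnograms=hypnograms)


def replace_cfg(cfg: CohortConfig, **kw) -> CohortConfig:
    from dataclasses import replace
    return replace(cfg, **kw)


def _maps_from_model(cfg, subjects, eeg_labels, theta_gain, spindle_rate,
                     env_gain, swa_slope, patches, rng):
    """Band-power / spindle-metric maps drawn from the generative parameters
    without waveform synthesis (log-normal measurement noise on top)."""
    n, nch = len(subjects), len(eeg_labels)
    p = cfg.recording
    sig = cfg.map_noise_sigma
    b_theta = p.theta_power * np.exp(0.2 * rng.standard_normal(nch))
    b_swa = p.swa_base_power * np.exp(0.2 * rng.standard_normal(nch))
    b_env = 6.6 * np.exp(0.1 * rng.standard_normal(nch))
    minutes = cfg.total_sleep_min * 0.70   # artifact-free N2+N3 share
    maps = {m: {} for m in SLEEP_MEASURES}

    def patch_mask(measure):
        pat = patches.get(measure)
        if pat is None:
            return np.ones(nch, dtype=bool)
        return np.array([l in pat for l in eeg_labels])

    pm_theta = patch_mask("rem_theta")
    for cond in ("trauma", "neutral"):
        g = np.array([theta_gain[(s, cond)] for s in subjects])
        gain2 = np.where(pm_theta[None, :], g[:, None] ** 2, 1.0)
        signal = (cfg.theta_background_frac
                  + (1 - cfg.theta_background_frac) * gain2)
        maps["rem_theta"][cond] = (b_theta[None, :] * signal
                                   * np.exp(sig * rng.standard_normal((n, nch))))

        slope = np.array([swa_slope[(s, cond)] for s in subjects])
        maps["swa"][cond] = (b_swa[None, :]
                             * (slope[:, None] / p.swa_within_slope) ** 0.5
                             * np.exp(sig * rng.standard_normal((n, nch))))

        rate = np.array([spindle_rate[(s, cond)] for s in subjects])
        pm = patch_mask("spindle_count")
        lam = np.where(pm[None, :], rate[:, None], cfg.spindle_rate_base) \
            * minutes
        maps["spindle_count"][cond] = rng.poisson(lam).astype(float)

        e = np.array([env_gain[(s, cond)] for s in subjects])
        pm = patch_mask("spindle_envelope")
        egain = np.where(pm[None, :], e[:, None], 1.0)
        maps["spindle_envelope"][cond] = (
            b_env[None, :] * egain
            * np.exp(0.5 * sig * rng.standard_normal((n, nch))))
    return maps


def _make_diary(subjects, counts, rng) -> pd.DataFrame:
    """Six-day diary: qualifying entries (sudden & film-related) matching the
    planted totals, plus distractor entries the filters must reject."""
    day_w = np.array([0.30, 0.22, 0.16, 0.13, 0.11, 0.08])
    rows = []
    for s, c in zip(subjects, counts):
        days = rng.choice(np.arange(1, 7), size=int(c), p=day_w)
        for d in sorted(days):
            rows.append(_diary_row(s, int(d), True, True, rng))
        for _ in range(int(rng.integers(0, 3))):
            kind = rng.integers(0, 3)
            sudden = kind != 0
            related = kind != 1
            day = int(rng.integers(1, 7)) if kind != 2 else 7
            rows.append(_diary_row(s, day, sudden, related, rng))
    df = pd.DataFrame(rows, columns=["subject", "day", "timestamp", "modality",
                                     "sudden", "film_related", "distress",
                                     "arousal"])
    return df.sort_values(["subject", "day", "timestamp"]).reset_index(drop=True)


def _diary_row(s, day, sudden, related, rng):
    hour = int(rng.integers(8, 23))
    minute = int(rng.integers(0, 60))
    return {
        "subject": s, "day": day,
        "timestamp": f"day{day} {hour:02d}:{minute:02d}",
        "modality": ["image", "sound", "thought"][rng.integers(0, 3)],
        "sudden": bool(sudden), "film_related": bool(related),
        "distress": float(np.round(rng.uniform(20, 90), 1)),
        "arousal": float(np.round(rng.uniform(20, 90), 1)),
    }


def _make_sam(subjects, rng) -> pd.DataFrame:
    """Pre/post pictorial mood and arousal ratings (1-9) per condition:
    the trauma film lowers mood and raises arousal; the neutral film leaves
    mood unchanged and lets arousal settle slightly."""
    rows = []
    for s in subjects:
        for cond in ("trauma", "neutral"):
            mood_pre = int(np.clip(round(rng.normal(7.0, 1.0)), 1, 9))
            aro_pre = int(np.clip(round(rng.normal(3.5, 1.0)), 1, 9))
            d_mood = -2.5 if cond == "trauma" else 0.0
            d_aro = 2.0 if cond == "trauma" else -1.0
            mood_post = int(np.clip(round(mood_pre + d_mood
                                          + rng.normal(0, 0.8)), 1, 9))
            aro_post = int(np.clip(round(aro_pre + d_aro
                                         + rng.normal(0, 0.8)), 1, 9))
            rows.append({"subject": s, "condition": cond, "time": "pre",
                         "mood": mood_pre, "arousal": aro_pre})
            rows.append({"subject": s, "condition": cond, "time": "post",
                         "mood": mood_post, "arousal": aro_post})
    return pd.DataFrame(rows)


def _make_affect(subjects, aff_change, cfg, rng) -> pd.DataFrame:
    rows = []
    for s, ch in zip(subjects, aff_change):
        pre = float(np.clip(np.round(
            rng.normal(cfg.affect_pre_mean, cfg.affect_pre_sd)), 10, 45))
        post = float(np.clip(np.round(pre + ch), 10, 50))
        rows.append({"subject": s, "time": "pre", "na_sum": pre})
        rows.append({"subject": s, "time": "post", "na_sum": post})
    return pd.DataFrame(rows)
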