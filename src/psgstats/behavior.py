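"""Behavioural and autonomic outcome scoring.

Minute-wise heart rate from beat timestamps, the peak-window heart-rate mean,
intrusion-diary filtering and totals, provocation-task negative-affect change,
and intra-individual trauma-minus-neutral change scores.

Film minutes are 1-based throughout ("minutes seven to nine" means the 7th,
8th and 9th minute of the 12-minute film, i.e. seconds [360, 540)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIARY_COLUMNS = ["subject", "day", "timestamp", "modality", "sudden",
                 "film_related", "distress", "arousal"]

PANAS_RANGE = (10, 50)


@dataclass
class DiaryEntry:
    subject: str
    day: int
    timestamp: str
    modality: str       # image | sound | thought
    sudden: bool
    film_related: bool
    distress: float     # 0-100
    arousal: float      # 0-100


def minute_hr(beats: np.ndarray, duration_min: int) -> np.ndarray:
    """Per-minute heart rate (bpm) from sorted beat timestamps in seconds.

    Each inter-beat interval contributes an instantaneous rate ``60 / RR``
    assigned to the minute containing the interval midpoint; the minute value
    is the mean of those rates. Minutes backed by fewer than 2 beats are
    reported as nan (missing).
    """
    beats = np.asarray(beats, dtype=float)
    if beats.ndim != 1:
        raise ValueError("beats must be a 1-D timestamp array")
    if np.any(np.diff(beats) < 0) or np.any(beats < 0):
        raise ValueError("beats must be sorted and non-negative")
    out = np.full(duration_min, np.nan)
    if beats.size < 2:
        return out
    rr = np.diff(beats)
    mid = beats[:-1] + rr / 2
    rate = 60.0 / rr
    minute = np.floor(mid / 60.0).astype(int)
    for m in range(duration_min):
        sel = minute == m
        # a minute needs >= 2 beats, i.e. >= 1 full interval inside it
        if sel.sum() >= 1 and np.sum((beats >= 60 * m) & (beats < 60 * (m + 1))) >= 2:
            out[m] = rate[sel].mean()
    return out


def minute_ttests(hr_a: np.ndarray, hr_b: np.ndarray):
    """Paired two-sided t-test per minute between two condition matrices.

    Rows are subjects, columns minutes; subjects with a missing value in a
    minute are dropped for that minute. Returns ``(t, p)`` arrays. Minutes
    with zero variance of the differences give ``p = 1`` with a warning.
    """
    hr_a = np.asarray(hr_a, dtype=float)
    hr_b = np.asarray(hr_b, dtype=float)
    if hr_a.shape != hr_b.shape:
        raise ValueError("matrices must have equal shape")
    n_min = hr_a.shape[1]
    t = np.full(n_min, np.nan)
    p = np.full(n_min, np.nan)
    for m in range(n_min):
        ok = ~np.isnan(hr_a[:, m]) & ~np.isnan(hr_b[:, m])
        if ok.sum() < 3:
            raise ValueError(f"minute {m}: fewer than 3 complete pairs")
        d = hr_a[ok, m] - hr_b[ok, m]
        if d.std(ddof=1) == 0:
            warnings.warn(f"minute {m}: zero variance of differences")
            t[m], p[m] = 0.0, 1.0
        else:
            res = stats.ttest_rel(hr_a[ok, m], hr_b[ok, m])
            t[m], p[m] = res.statistic, res.pvalue
    return t, p


def hr_window_mean(hr: np.ndarray, window: tuple[int, int] = (7, 9)) -> float:
    """Mean bpm over an inclusive window of 1-based film minutes.

    Returns nan with a warning when any window minute is missing.
    """
    hr = np.asarray(hr, dtype=float)
    lo, hi = window
    if not 1 <= lo <= hi <= hr.size:
        raise ValueError("window out of range of the heart-rate series")
    vals = hr[lo - 1:hi]
    if np.any(np.isnan(vals)):
        warnings.warn("missing minute inside HR window; mean undefined")
        return float("nan")
    return float(vals.mean())


def intrusion_total(entries, subject=None) -> int:
    """Total qualifying diary intrusions over the six-day period.

    Qualifying entries are sudden AND film-related, with day in 1..6; anything
    else (deliberate recollections, film-unrelated memories, out-of-window
    days) is excluded. Accepts a DataFrame with the diary columns or an
    iterable of :class:`DiaryEntry`.
    """
    if isinstance(entries, pd.DataFrame):
        df = entries
        if subject is not None:
            df = df[df["subject"] == subject]
        sel = (df["sudden"].astype(bool) & df["film_related"].astype(bool)
               & df["day"].between(1, 6))
        return int(sel.sum())
    total = 0
    for e in entries:
        if subject is not None and e.subject != subject:
            continue
        if e.sudden and e.film_related and 1 <= e.day <= 6:
            total += 1
    return total


def affect_change(pre: float, post: float) -> float:
    """Negative-affect change (post minus pre) in PANAS-NA sum points."""
    for v in (pre, post):
        if not PANAS_RANGE[0] <= v <= PANAS_RANGE[1]:
            raise ValueError(f"PANAS-NA sum {v} outside {PANAS_RANGE}")
    return float(post) - float(pre)


def change_score(x_trauma, x_neutral):
    """Intra-individual change score: trauma minus neutral.

    Positive values mean an increase after the trauma film. Missing input
    (None or nan) propagates to a missing output.
    """
    if x_trauma is None or x_neutral is None:
        return None
    x_trauma = np.asarray(x_trauma, dtype=float)
    x_neutral = np.asarray(x_neutral, dtype=float)
    out = x_trauma - x_neutral
    return float(out) if out.ndim == 0 else out


def provocation_presses_total(presses) -> int:
    """Total spacebar-indicated intrusions over the reminder images.

    Ingested and summed for completeness; the primary prediction targets are
    the diary total and the negative-affect change, not this count.
    """
    presses = np.asarray(list(presses), dtype=int)
    if np.any(presses < 0):
        raise ValueError("press counts must be non-negative")
    return int(presses.sum())


def paired_prepost_t(pre: np.ndarray, post: np.ndarray):
    """Two-sided paired t-test on pre/post score vectors (e.g. SAM ratings)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = ~np.isnan(pre) & ~np.isnan(post)
    res = stats.ttest_rel(pre[ok], post[ok])
    return float(res.statistic), float(res.pvalue)
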