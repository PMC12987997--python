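"""File formats: EDF recordings, and CSV/TSV tables for everything else.

The EDF writer is a deliberately minimal implementation of the classic
EDF header + int16 data-record layout (one-second records, one gain per
channel); reading goes through mne's bundled EDF reader, which also serves
as an independent check on the writer. Quantisation to 16 bits bounds the
round-trip error at (phys_max - phys_min) / 65535 per channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Hypnogram, Recording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: Recording, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write a recording as classic EDF with 1-s data records, in microvolts."""
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = rec.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    if n_rec * spr != n_samp:
        pad = np.repeat(data[:, -1:], n_rec * spr - n_samp, axis=1)
        data = np.concatenate([data, pad], axis=1)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    dig = np.round((data - pmin[:, None]) * scale[:, None]
                   + _EDF_DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad_ascii("0", 8))
        fh.write(_pad_ascii(patient_id, 80))
        fh.write(_pad_ascii(recording_id, 80))
        fh.write(_pad_ascii("01.01.00", 8))
        fh.write(_pad_ascii("00.00.00", 8))
        fh.write(_pad_ascii(256 * (1 + n_ch), 8))
        fh.write(_pad_ascii("", 44))
        fh.write(_pad_ascii(n_rec, 8))
        fh.write(_pad_ascii(1, 8))
        fh.write(_pad_ascii(n_ch, 4))
        for lab in rec.labels:
            fh.write(_pad_ascii(lab, 16))
        for _ in rec.labels:
            fh.write(_pad_ascii("", 80))           # transducer
        for _ in rec.labels:
            fh.write(_pad_ascii("uV", 8))          # physical dimension
        for v in pmin:
            fh.write(_pad_ascii(f"{v:.6g}"[:8], 8))
        for v in pmax:
            fh.write(_pad_ascii(f"{v:.6g}"[:8], 8))
        for _ in rec.labels:
            fh.write(_pad_ascii(_EDF_DIG_MIN, 8))
        for _ in rec.labels:
            fh.write(_pad_ascii(_EDF_DIG_MAX, 8))
        for _ in rec.labels:
            fh.write(_pad_ascii("", 80))           # prefiltering
        for _ in rec.labels:
            fh.write(_pad_ascii(spr, 8))
        for _ in rec.labels:
            fh.write(_pad_ascii("", 32))
        # data records: per record, per signal, int16 little-endian
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def infer_channel_type(label: str) -> str:
    u = label.upper()
    if u in ("M1", "M2", "A1", "A2"):
        return "mastoid"
    for prefix, t in (("EOG", "EOG"), ("EMG", "EMG"), ("ECG", "ECG"),
                      ("EKG", "ECG")):
        if u.startswith(prefix):
            return t
    return "EEG"


def read_edf(path, types=None) -> Recording:
    """Read an EDF recording via mne; channel types inferred from labels
    unless given explicitly."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    labels = list(raw.ch_names)
    if types is None:
        types = [infer_channel_type(l) for l in labels]
    return Recording(data, float(raw.info["sfreq"]), labels, list(types))


# ---------------------------------------------------------------------------
# text tables
# ---------------------------------------------------------------------------

def write_hypnogram(path, hyp: Hypnogram) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "stage": hyp.stages,
        "artifact": hyp.artifact.astype(int),
    })
    df.to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path)
    df = df.sort_values("epoch_index")
    return Hypnogram(df["stage"].to_numpy(dtype=object),
                     df["artifact"].to_numpy(dtype=bool))


def write_beats(path, beats: np.ndarray) -> None:
    pd.DataFrame({"t_sec": np.asarray(beats, dtype=float)}).to_csv(
        path, index=False)


def read_beats(path) -> np.ndarray:
    return pd.read_csv(path)["t_sec"].to_numpy(dtype=float)


def write_diary(path, diary: pd.DataFrame) -> None:
    diary.to_csv(path, index=False)


def read_diary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sudden", "film_related"):
        df[col] = df[col].astype(bool)
    return df


def write_ground_truth(path, truth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def write_band_power_tsv(path, values: dict) -> None:
    """``values``: {(subject, condition, channel): power}."""
    rows = [{"subject": s, "condition": c, "channel": ch, "value": v}
            for (s, c, ch), v in values.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_events_tsv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=["subject", "condition", "channel",
                                "onset_s", "offset_s", "peak_env"]
                 ).to_csv(path, sep="\t", index=False)


def write_spectrum_csv(path, spec) -> None:
    """Wide CSV: one row per channel, one column per frequency bin."""
    pd.DataFrame(spec.power, index=spec.labels,
                 columns=[f"{f:.7g}" for f in spec.freqs]).to_csv(
        path, index_label="channel")


def write_spindle_metrics_tsv(path, rows: list[dict]) -> None:
    """Per subject x condition x channel metrics table."""
    pd.DataFrame(rows, columns=["subject", "condition", "channel", "count",
                                "density", "envelope"]
                 ).to_csv(path, sep="\t", index=False)
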