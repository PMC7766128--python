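"""Plain EDF reading/writing plus event-table CSV companions.

A deliberately small EDF implementation (classic EDF, 16-bit samples,
1 s data records); the final record is zero-padded and the true sample
count is kept in the header's reserved field so round trips preserve
length.  Events/trials travel in a sibling CSV with columns
(onset_s, duration_s, label).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MontageSpec
from .recording import EEGRecording, EVENT_COLUMNS

_HDR_FIXED = 256
_HDR_PER_SIGNAL = 256


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")[:width]
    return b.ljust(width)


def events_path(edf_path) -> Path:
    p = Path(edf_path)
    return p.with_name(p.stem + "_events.csv")


def write_events(path, events: pd.DataFrame) -> None:
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} lacks columns {missing}")
    return df


def write_edf(path, recording: EEGRecording, with_events: bool = True) -> None:
    """Write a recording as classic EDF (plus `<stem>_events.csv` if events)."""
    fs = recording.sfreq
    ns_per_record = int(round(fs))
    if abs(ns_per_record - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.n_channels
    n_samples = recording.n_samples
    n_records = int(np.ceil(n_samples / ns_per_record))

    # Per-channel symmetric physical range covering the data.  The range is
    # re-parsed from its 8-char header representation so the digitization
    # scale matches what a reader will reconstruct.
    phys_max = np.ceil(np.maximum(np.max(np.abs(recording.data), axis=1), 1.0) * 1.0001)
    dig_max = 32767

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(_HDR_FIXED + _HDR_PER_SIGNAL * n_ch, 8),
        _field(f"nsamples={n_samples}", 44),
        _field(n_records, 8),
        _field("1", 8),
        _field(n_ch, 4),
    ])
    header += b"".join(_field(name, 16) for name in recording.montage.channel_names)
    header += b"".join(_field("EEG electrode", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(-dig_max, 8) for _ in range(n_ch))
    header += b"".join(_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(ns_per_record, 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    padded = np.zeros((n_ch, n_records * ns_per_record))
    padded[:, :n_samples] = recording.data
    scale = dig_max / phys_max
    digital = np.rint(padded * scale[:, None]).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            block = digital[:, r * ns_per_record:(r + 1) * ns_per_record]
            f.write(block.tobytes())  # channel-major within the record

    if with_events and len(recording.events):
        write_events(events_path(path), recording.events)


def read_edf(path) -> dict:
    """Parse an EDF file into labels, sampling rate, and a float data array."""
    with open(path, "rb") as f:
        raw = f.read()
    if len(raw) < _HDR_FIXED:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def txt(a, b):
        return raw[a:b].decode("ascii", errors="replace").strip()

    reserved = txt(192, 236)
    n_records = int(txt(236, 244))
    record_dur = float(txt(244, 252))
    n_ch = int(txt(252, 256))

    off = _HDR_FIXED
    def sig_fields(width):
        nonlocal off
        vals = [txt(off + i * width, off + (i + 1) * width) for i in range(n_ch)]
        off += width * n_ch
        return vals

    labels = sig_fields(16)
    sig_fields(80)          # transducer
    sig_fields(8)           # physical dimension
    phys_min = [float(v) for v in sig_fields(8)]
    phys_max = [float(v) for v in sig_fields(8)]
    dig_min = [int(v) for v in sig_fields(8)]
    dig_max = [int(v) for v in sig_fields(8)]
    sig_fields(80)          # prefilter
    ns = [int(v) for v in sig_fields(8)]
    sig_fields(32)          # reserved

    if len(set(ns)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    ns_per_record = ns[0]
    fs = ns_per_record / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=_HDR_FIXED + _HDR_PER_SIGNAL * n_ch)
    body = body[:n_records * n_ch * ns_per_record].reshape(n_records, n_ch, ns_per_record)
    data = np.swapaxes(body, 0, 1).reshape(n_ch, -1).astype(float)
    for c in range(n_ch):
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        data[c] = (data[c] - dig_min[c]) * gain + phys_min[c]

    if reserved.startswith("nsamples="):
        true_n = int(reserved.split("=", 1)[1])
        data = data[:, :true_n]
    return {"labels": labels, "fs": fs, "data": data}


def read_eeg(path, montage: MontageSpec | None = None) -> EEGRecording:
    """Read an EDF as an EEGRecording, reordered to montage order.

    Raises with an explicit message if a montage channel is missing or the
    sampling rate differs from the montage's.
    """
    montage = montage or MontageSpec()
    parsed = read_edf(path)
    if abs(parsed["fs"] - montage.sampling_rate) > 1e-6:
        raise ValueError(
            f"{path}: sampling rate {parsed['fs']:g} Hz, montage requires "
            f"{montage.sampling_rate:g} Hz")
    index = {lab: i for i, lab in enumerate(parsed["labels"])}
    missing = [n for n in montage.channel_names if n not in index]
    if missing:
        raise ValueError(f"{path}: missing montage channels {missing}")
    rows = [index[n] for n in montage.channel_names]
    data = parsed["data"][rows]

    ev_path = events_path(path)
    events = read_events(ev_path) if ev_path.exists() else None
    rec = EEGRecording(data, montage)
    if events is not None:
        rec.events = events
    return rec


def write_eeg(path, recording: EEGRecording) -> None:
    write_edf(path, recording)
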