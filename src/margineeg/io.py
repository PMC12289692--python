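"""File I/O: a minimal EDF writer/reader and the internal epoch container.

EDF (European Data Format) stores multichannel biosignals as 16-bit integers
with per-channel physical scaling behind a fixed-width ASCII header.  Only the
subset needed for continuous EEG is implemented: one fixed-rate signal group,
1-second data records, integer sampling rate.  Cue events are written to a
JSON sidecar (``<file>.events.json``) since plain EDF has no annotation
channel.

The epoch container is a directory holding ``data.npy`` (trials x channels x
samples, float64, microvolt) plus a ``meta.json`` sidecar with labels,
sampling rate and bookkeeping indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EpochSet
from .synth import RawRecording

__all__ = ["write_edf", "read_edf", "save_epochs", "load_epochs"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path) -> Path:
    """Write the recording as 16-bit EDF (+ events sidecar); returns the path.

    Quantization: each channel is scaled to its own physical min/max, so the
    round-trip error is bounded by (max-min)/65535 per channel.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = np.asarray(recording.data, dtype=float)
    ns, n_samples = data.shape
    n_records = n_samples // spr  # trailing partial record dropped
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0

    header = b"".join([
        _field("0", 8),
        _field(f"subject {recording.subject_id}", 80),
        _field("margineeg synthetic recording", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
        b"".join(_field(nm, 16) for nm in recording.channel_names),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field("uV", 8) for _ in range(ns)),
        b"".join(_field(f"{v:.6g}", 8) for v in pmin),
        b"".join(_field(f"{v:.6g}", 8) for v in pmax),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_field("HP:4Hz", 80) for _ in range(ns)),
        b"".join(_field(str(spr), 8) for _ in range(ns)),
        b"".join(_field("", 32) for _ in range(ns)),
    ])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = data[:, r * spr:(r + 1) * spr]
            dig = np.rint((block - pmin[:, None]) / scale[:, None] + _DIG_MIN)
            fh.write(dig.astype("<i2").tobytes())
    sidecar = {"fs": fs, "subject_id": recording.subject_id,
               "events": [[int(o), int(l)] for o, l in recording.events]}
    Path(str(path) + ".events.json").write_text(json.dumps(sidecar))
    return path


def read_edf(path) -> RawRecording:
    """Read an EDF written by :func:`write_edf` (one rate, 1-s records)."""
    path = Path(path)
    raw = path.read_bytes()

    def f(off, width):
        return raw[off:off + width].decode("ascii").strip()

    ns = int(f(252, 4))
    n_records = int(f(236, 8))
    duration = float(f(244, 8))
    off = 256

    def per_signal(width):
        nonlocal off
        vals = [f(off + i * width, width) for i in range(ns)]
        off += ns * width
        return vals

    labels = per_signal(16)
    per_signal(80)              # transducer
    per_signal(8)               # physical dimension
    pmin = np.array([float(v) for v in per_signal(8)])
    pmax = np.array([float(v) for v in per_signal(8)])
    dmin = np.array([float(v) for v in per_signal(8)])
    dmax = np.array([float(v) for v in per_signal(8)])
    per_signal(80)              # prefilter
    spr = np.array([int(v) for v in per_signal(8)])
    per_signal(32)              # reserved
    if len(set(spr)) != 1:
        raise ValueError("mixed sampling rates are not supported")
    spr = int(spr[0])
    fs = spr / duration

    body = np.frombuffer(raw[256 * (ns + 1):], dtype="<i2")
    body = body[:n_records * ns * spr].reshape(n_records, ns, spr)
    dig = body.transpose(1, 0, 2).reshape(ns, n_records * spr).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[:, None]) * scale[:, None] + pmin[:, None]

    events: list[tuple[int, int]] = []
    subject_id = 0
    sidecar = Path(str(path) + ".events.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        events = [(int(o), int(l)) for o, l in meta["events"]]
        subject_id = int(meta.get("subject_id", 0))
        fs = float(meta.get("fs", fs))
    return RawRecording(data=data, fs=fs, channel_names=labels,
                        events=events, subject_id=subject_id)


def save_epochs(epochs: EpochSet, out_dir) -> Path:
    """Epoch container: data.npy + meta.json in a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "data.npy", epochs.data)
    meta = {
        "labels": epochs.labels.tolist(),
        "fs": epochs.fs,
        "subject_id": int(epochs.subject_id),
        "kept_trial_idx": epochs.kept_trial_idx.tolist(),
        "channel_names": epochs.channel_names,
        "dropped_events": list(epochs.dropped_events),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta))
    return out_dir


def load_epochs(in_dir) -> EpochSet:
    in_dir = Path(in_dir)
    data = np.load(in_dir / "data.npy")
    meta = json.loads((in_dir / "meta.json").read_text())
    return EpochSet(data=data, labels=np.asarray(meta["labels"], dtype=int),
                    fs=float(meta["fs"]), subject_id=int(meta["subject_id"]),
                    kept_trial_idx=np.asarray(meta["kept_trial_idx"], dtype=int),
                    channel_names=meta["channel_names"],
                    dropped_events=list(meta["dropped_events"]))
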