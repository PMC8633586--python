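"""File interchange: EDF recordings, tab-separated event and feature
tables, and epoch archives.

Reading EDF goes through mne. Writing uses a minimal EDF encoder (16-bit
samples, 1-second data records, physical unit microvolts) sufficient for
round-tripping synthetic sessions; quantization error is bounded by the
per-channel physical range divided by 2^16.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording, TrialEpoch

__all__ = [
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "write_features",
    "read_features",
    "save_epochs",
    "load_epochs",
]

EVENT_COLUMNS = ["onset", "duration", "task", "phase", "block", "subject"]


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording as EDF (one signal per channel, physical unit uV).

    The sampling rate must be a whole number of samples per second; the
    signal is zero-padded to a whole number of 1 s data records.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr < 1:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(f"subject-{rec.subject}", 80),
            _ascii("synthetic VMI session", 80),
            _ascii("01.01.20", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (16, rec.channel_labels),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [dig_min] * n_ch),
        (8, [dig_max] * n_ch),
        (80, [""] * n_ch),
        (8, [spr] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, subject: int | None = None) -> Recording:
    """Read an EDF file into a Recording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    labels = list(raw.ch_names)
    if subject is None:
        subject = 0
        info = raw.info.get("subject_info") or {}
        his_id = dict(info).get("his_id", "") if info else ""
        if his_id.startswith("subject-"):
            try:
                subject = int(his_id.split("-", 1)[1])
            except ValueError:
                pass
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject=int(subject),
    )


# ---------------------------------------------------------------------------
# TSV tables


def write_events(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    return events[EVENT_COLUMNS]


def write_features(path: str | Path, features: pd.DataFrame) -> Path:
    path = Path(path)
    features.to_csv(path, sep="\t", index=False)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# epoch archives


def save_epochs(path: str | Path, epochs: list[TrialEpoch]) -> Path:
    """Serialize epochs to one .npz archive plus a JSON sidecar describing
    each epoch (subject, block, task, phase, fs, channels)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = {f"epoch_{i:05d}": ep.data for i, ep in enumerate(epochs)}
    np.savez_compressed(path, **arrays)
    meta = [
        {
            "key": f"epoch_{i:05d}",
            "fs": ep.fs,
            "task": ep.task,
            "phase": ep.phase,
            "subject": ep.subject,
            "block": ep.block,
            "channel_labels": list(ep.channel_labels),
        }
        for i, ep in enumerate(epochs)
    ]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_epochs(path: str | Path) -> list[TrialEpoch]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    epochs = []
    with np.load(path) as npz:
        for m in meta:
            epochs.append(
                TrialEpoch(
                    data=npz[m["key"]],
                    fs=m["fs"],
                    channel_labels=m["channel_labels"],
                    task=m["task"],
                    phase=m["phase"],
                    subject=m["subject"],
                    block=m["block"],
                )
            )
    return epochs
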