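"""File IO: EDF and BrainVision reading (via mne), a minimal EDF writer,
marker sidecar CSVs, ground-truth JSON, and YAML config round-tripping.

Reading goes through mne, which parses both EDF and BrainVision natively.
Writing EDF is done by a small self-contained encoder (16-bit EDF, 1 s data
records) because no EDF export backend is part of the dependency set; the
writer is round-trip tested against mne's reader.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .records import ECGRecord, EEGRecording

__all__ = [
    "write_edf",
    "read_ecg",
    "read_eeg",
    "write_markers_csv",
    "read_markers_csv",
    "write_ground_truth",
    "load_config_yaml",
    "dump_config_yaml",
]


def _pad(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    data: np.ndarray,
    fs: float,
    ch_names: list[str],
    path: str | Path,
    physical_dim: str = "uV",
) -> Path:
    """Write channels x samples data as a 16-bit EDF file with 1 s records.

    ``fs`` must be an integer number of samples per second. Physical
    scaling per channel spans the signal's range; a trailing partial second
    is dropped.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != len(ch_names):
        raise ValueError("one channel name per data row required")
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = data.shape[1] // spr
    if n_rec == 0:
        raise ValueError("less than one second of data")
    ns = len(ch_names)
    path = Path(path)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * gain[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields: list[tuple[int, list[str]]] = [
        (16, [ch for ch in ch_names]),
        (80, ["" for _ in ch_names]),
        (8, [physical_dim for _ in ch_names]),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [str(dmin) for _ in ch_names]),
        (8, [str(dmax) for _ in ch_names]),
        (80, ["" for _ in ch_names]),
        (8, [str(spr) for _ in ch_names]),
        (32, ["" for _ in ch_names]),
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            sl = digital[:, r * spr : (r + 1) * spr]
            fh.write(sl.tobytes())
    return path


def _read_raw(path: str | Path):
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        return mne.io.read_raw_edf(path, preload=True, verbose="error")
    if path.suffix.lower() == ".vhdr":
        return mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    raise ValueError(f"unsupported recording format: {path.suffix}")


def read_ecg(path: str | Path, channel: str | int = 0) -> ECGRecord:
    """Read single-lead ECG from EDF or from CSV with time_s,voltage columns."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"time_s", "voltage"} <= set(df.columns):
            raise ValueError("ECG CSV needs 'time_s' and 'voltage' columns")
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("ECG CSV must be uniformly sampled")
        return ECGRecord(df["voltage"].to_numpy(dtype=float), 1.0 / dt[0],
                         meta={"path": str(path)})
    raw = _read_raw(path)
    idx = channel if isinstance(channel, int) else raw.ch_names.index(channel)
    sig = raw.get_data()[idx]
    return ECGRecord(sig, raw.info["sfreq"], meta={"path": str(path)})


def read_eeg(path: str | Path, bandwidth: tuple[float, float] = (0.5, 40.0)) -> EEGRecording:
    """Read a multichannel EEG recording from EDF or BrainVision (.vhdr).

    mne loads in volts for EEG channel types; values are returned in uV.
    """
    raw = _read_raw(path)
    data = raw.get_data()
    # mne scales EDF 'uV' physical dims to volts internally
    if np.nanmax(np.abs(data)) < 0.1:
        data = data * 1e6
    return EEGRecording(
        data, raw.info["sfreq"], list(raw.ch_names),
        bandwidth=bandwidth, meta={"path": str(path)},
    )


def write_markers_csv(markers: pd.DataFrame, path: str | Path) -> Path:
    """Sidecar marker file: onset_s,label (labels S1|S2)."""
    path = Path(path)
    markers[["onset_s", "label"]].to_csv(path, index=False)
    return path


def read_markers_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"onset_s", "label"} <= set(df.columns):
        raise ValueError("marker CSV needs 'onset_s' and 'label' columns")
    return df


def write_ground_truth(truth: dict[str, Any], path: str | Path) -> Path:
    """Per-session ground-truth JSON (generating parameters and latents)."""
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(truth, indent=2, default=_default))
    return path


def load_config_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config YAML must map keys to values")
    return cfg


def dump_config_yaml(cfg: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
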