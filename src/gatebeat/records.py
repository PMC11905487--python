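"""Shared in-memory containers for continuous physiological recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ECGRecord", "EEGRecording"]


@dataclass
class ECGRecord:
    """Continuous single-lead ECG.

    Parameters
    ----------
    signal : array of voltage samples (mV).
    fs : sampling rate in Hz.
    meta : provenance metadata. Synthetic records carry the ground-truth
        R-wave times under ``meta["true_r_times"]`` (seconds).
    """

    signal: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("ECG signal must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.signal.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.fs


@dataclass
class EEGRecording:
    """Multi-channel EEG, channels x samples, in microvolts.

    ``bandwidth`` records the acquisition band-pass (Hz); band-power
    requests outside it are refused downstream.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    bandwidth: tuple[float, float] = (0.5, 40.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by 10-20 label."""
        try:
            idx = self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.data[idx]
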