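"""Per-channel band-power features from resting EEG.

These 32 channels x 5 bands = 160 log band powers form the predictor matrix
for the all-relevant feature-selection stage. Band edges follow clinical
convention, truncated at the 40 Hz acquisition filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import EEGRecording

__all__ = ["DEFAULT_BANDS", "BandPowerMatrix", "resting_band_powers"]

#: Conventional clinical EEG bands (Hz), truncated at the 40 Hz filter edge.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class BandPowerMatrix:
    """Absolute band power per channel (uV^2) and its natural log.

    ``power`` and ``log_power`` are channels x bands DataFrames; zero power
    maps to -inf log power.
    """

    power: pd.DataFrame
    log_power: pd.DataFrame
    bands: dict[str, tuple[float, float]]

    def features(self) -> pd.Series:
        """Flatten to a ``{channel}_{band}`` log-power feature vector."""
        out = {}
        for ch in self.log_power.index:
            for band in self.log_power.columns:
                out[f"{ch}_{band}"] = self.log_power.loc[ch, band]
        return pd.Series(out)


def resting_band_powers(
    recording: EEGRecording,
    bands: dict[str, tuple[float, float]] | None = None,
    *,
    seg_s: float = 4.0,
) -> BandPowerMatrix:
    """Welch band powers for every channel.

    4 s Hann segments with 50% overlap; band power is the PSD integral
    between the band edges (half-open at the top so adjacent bands never
    double count a bin).
    """
    bands = dict(bands or DEFAULT_BANDS)
    lo_rec, hi_rec = recording.bandwidth
    for name, (lo, hi) in bands.items():
        if lo >= hi:
            raise ValueError(f"band {name!r} has non-positive width")
        if lo < lo_rec or hi > hi_rec:
            raise ValueError(
                f"band {name!r} [{lo}, {hi}] Hz outside recording bandwidth "
                f"[{lo_rec}, {hi_rec}] Hz"
            )
    if recording.duration < 60.0:
        raise ValueError("need at least 60 s of resting EEG")

    nper = min(int(round(seg_s * recording.fs)), recording.data.shape[1])
    freqs, psd = sps.welch(
        recording.data.astype(float), fs=recording.fs, window="hann",
        nperseg=nper, noverlap=nper // 2, axis=1,
    )
    df = freqs[1] - freqs[0]
    power = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        power[name] = psd[:, mask].sum(axis=1) * df
    pw = pd.DataFrame(power, index=list(recording.ch_names))
    with np.errstate(divide="ignore"):
        logpw = np.log(pw)
    return BandPowerMatrix(power=pw, log_power=logpw, bands=bands)
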