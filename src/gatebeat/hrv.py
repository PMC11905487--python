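"""Frequency-domain heart-rate-variability analysis from raw ECG.

The chain is: R-peak detection (Pan-Tompkins-style), inter-beat-interval
(IBI) series in milliseconds, ectopic correction against a local median,
cubic interpolation onto a uniform 4 Hz grid, linear detrend, Welch power
spectral density, and band integration over the canonical short-term bands
LF = [0.04, 0.15) Hz and HF = [0.15, 0.40] Hz. Band powers are reported in
ms^2 together with their natural logarithms, which normalize the heavily
right-skewed power distributions. Respiration frequency is estimated from
the ECG itself (ECG-derived respiration, EDR) via the respiratory amplitude
modulation of the R wave.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

from .records import ECGRecord

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "IBISeries",
    "HRVResult",
    "NoBeatsError",
    "SignalQualityError",
    "detect_r_peaks",
    "compute_ibi",
    "correct_ibi",
    "hrv_band_powers",
    "estimate_edr",
    "hrv_from_ecg",
]

logger = logging.getLogger(__name__)

#: LF band, half-open at the top edge so 0.15 Hz is counted once (in HF).
LF_BAND = (0.04, 0.15)
#: HF band, closed.
HF_BAND = (0.15, 0.40)

_RESAMPLE_FS = 4.0     # Hz, uniform grid for spectral analysis
_WELCH_SEG_S = 120.0   # s, Welch segment length
_REFRACTORY_S = 0.2    # s, physiological minimum between R waves


class NoBeatsError(ValueError):
    """Raised when no heartbeats can be found in a signal."""


class SignalQualityError(ValueError):
    """Raised when too much of an IBI series needs correction."""


@dataclass
class IBISeries:
    """R-event times (s) and successive inter-beat intervals (ms).

    ``ibis[i] = (r_times[i+1] - r_times[i]) * 1000``; length is one less
    than the number of beats. ``corrected_mask`` flags intervals replaced by
    the ectopic-correction step.
    """

    r_times: np.ndarray
    ibis: np.ndarray
    corrected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.corrected_mask is None:
            self.corrected_mask = np.zeros(self.ibis.size, dtype=bool)
        if self.ibis.size != self.r_times.size - 1:
            raise ValueError("need exactly one interval per consecutive beat pair")
        if np.any(self.ibis <= 0):
            raise ValueError("all inter-beat intervals must be positive")

    @property
    def n_beats(self) -> int:
        return self.r_times.size

    @property
    def span(self) -> float:
        """Length of the covered interval in seconds."""
        return float(self.r_times[-1] - self.r_times[0])

    @property
    def mid_times(self) -> np.ndarray:
        """Time stamp of each interval (its end beat), in seconds."""
        return self.r_times[1:]


@dataclass
class HRVResult:
    """Frequency-domain HRV indices.

    ``lf_power``/``hf_power`` in ms^2, their natural logs, the EDR frequency
    in Hz (NaN when not computed), and the full (freqs, psd) pair used for
    the band integrals.
    """

    lf_power: float
    hf_power: float
    lf_log: float
    hf_log: float
    edr_freq: float
    edr_reliable: bool
    freqs: np.ndarray
    psd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lf_power_ms2": self.lf_power,
            "hf_power_ms2": self.hf_power,
            "lf_log": self.lf_log,
            "hf_log": self.hf_log,
            "edr_freq_hz": self.edr_freq,
            "edr_reliable": self.edr_reliable,
        }


def detect_r_peaks(ecg: ECGRecord) -> np.ndarray:
    """Locate R waves; returns strictly increasing sample indices.

    Pan-Tompkins-style energy detector: band-pass 5-25 Hz, differentiate,
    square, 150 ms moving-window integrate, adaptive threshold, then refine
    each detection to the local maximum of the band-passed signal. A 200 ms
    refractory period suppresses double detections.
    """
    x = ecg.signal
    if x.size < 10 * ecg.fs:
        raise ValueError("need at least 10 s of ECG")
    if not np.all(np.isfinite(x)):
        raise NoBeatsError("ECG contains NaN or infinite samples")
    if np.ptp(x) == 0:
        raise NoBeatsError("flat ECG signal, no beats found")

    fs = ecg.fs
    sos = sps.butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    thr = 0.2 * np.percentile(mwi, 99)
    cand, _ = sps.find_peaks(mwi, height=thr, distance=int(_REFRACTORY_S * fs))
    if cand.size == 0:
        raise NoBeatsError("no QRS energy above threshold")

    # refine: local max of |band-passed| within +/-60 ms
    half = int(round(0.06 * fs))
    peaks = np.empty(cand.size, dtype=int)
    for i, c in enumerate(cand):
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        peaks[i] = lo + int(np.argmax(np.abs(bp[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= _REFRACTORY_S * fs:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def compute_ibi(r_times: np.ndarray) -> IBISeries:
    """Successive differences of R times, in milliseconds."""
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size < 2:
        raise ValueError("need at least 2 beats to form an interval")
    return IBISeries(r_times=r_times, ibis=np.diff(r_times) * 1000.0)


def correct_ibi(ibi: IBISeries, rel_threshold: float = 0.3) -> IBISeries:
    """Replace ectopic/artefactual intervals by cubic interpolation.

    An interval deviating more than ``rel_threshold`` (relative) from the
    local median (window 11) is flagged and replaced by a cubic spline
    through the unflagged intervals. More than 20% flagged intervals is a
    quality failure.
    """
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must lie in (0, 1]")
    x = ibi.ibis
    from scipy.ndimage import median_filter

    med = median_filter(x, size=11, mode="nearest")
    bad = np.abs(x - med) > rel_threshold * med
    frac = bad.mean()
    if frac > 0.20:
        raise SignalQualityError(
            f"{frac:.0%} of intervals flagged for correction (limit 20%)"
        )
    if not bad.any():
        return IBISeries(ibi.r_times.copy(), x.copy(), np.zeros_like(bad))
    t = ibi.mid_times
    good = ~bad
    fixed = x.copy()
    if good.sum() >= 4:
        fixed[bad] = CubicSpline(t[good], x[good])(t[bad])
    else:  # too few anchors for a cubic; fall back to linear
        fixed[bad] = np.interp(t[bad], t[good], x[good])
    logger.info("corrected %d/%d intervals", int(bad.sum()), x.size)
    return IBISeries(ibi.r_times.copy(), fixed, bad)


def _uniform_series(t: np.ndarray, v: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of an unevenly sampled series onto a uniform grid."""
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    f = interp1d(t, v, kind="cubic", assume_sorted=True)
    return grid, f(grid)


def _welch_psd(v: np.ndarray, fs: float, seg_s: float) -> tuple[np.ndarray, np.ndarray]:
    nper = min(int(round(seg_s * fs)), v.size)
    return sps.welch(v, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
                     detrend=False)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float],
                closed_top: bool) -> float:
    df = freqs[1] - freqs[0]
    top = freqs <= band[1] if closed_top else freqs < band[1]
    mask = (freqs >= band[0]) & top
    return float(psd[mask].sum() * df)


def hrv_band_powers(ibi: IBISeries, *, resample_fs: float = _RESAMPLE_FS,
                    welch_seg_s: float = _WELCH_SEG_S) -> HRVResult:
    """Fast-Fourier spectral analysis of the IBI series.

    The IBI tachogram is cubically interpolated to a uniform ``resample_fs``
    grid, linearly detrended, and Welch-averaged (Hann window, 50% overlap).
    LF power integrates [0.04, 0.15) Hz, HF power [0.15, 0.40] Hz (half-open
    LF edge prevents double counting at 0.15 Hz); natural logs are stored.
    EDR is not computed here (see :func:`estimate_edr`).
    """
    if ibi.span < 120.0:
        raise ValueError("need at least 120 s of beats for spectral analysis")
    t, v = _uniform_series(ibi.mid_times, ibi.ibis, resample_fs)
    v = sps.detrend(v, type="linear")
    freqs, psd = _welch_psd(v, resample_fs, welch_seg_s)
    lf = _band_power(freqs, psd, LF_BAND, closed_top=False)
    hf = _band_power(freqs, psd, HF_BAND, closed_top=True)
    with np.errstate(divide="ignore"):
        return HRVResult(
            lf_power=lf, hf_power=hf,
            lf_log=float(np.log(lf)), hf_log=float(np.log(hf)),
            edr_freq=float("nan"), edr_reliable=False,
            freqs=freqs, psd=psd,
        )


def estimate_edr(
    ecg: ECGRecord,
    r_peaks: np.ndarray,
    *,
    band: tuple[float, float] = (0.10, 0.50),
    resample_fs: float = _RESAMPLE_FS,
    min_peak_factor: float = 5.0,
) -> tuple[float, bool]:
    """ECG-derived respiration frequency from R-wave amplitude modulation.

    The R-peak amplitude series is interpolated to a uniform grid,
    detrended, and its PSD maximised over ``band``. Returns
    ``(edr_freq_hz, reliable)``; the estimate is flagged unreliable when the
    spectral peak is less than ``min_peak_factor`` times the median in-band
    density (no clear respiratory modulation), but is still returned.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 30:
        raise ValueError("need at least 30 beats for EDR")
    r_t = r_peaks / ecg.fs
    if r_t[-1] - r_t[0] < 60.0:
        raise ValueError("need at least 60 s of beats for EDR")
    amps = ecg.signal[r_peaks]
    t, v = _uniform_series(r_t, amps, resample_fs)
    v = sps.detrend(v, type="linear")
    freqs, psd = _welch_psd(v, resample_fs, _WELCH_SEG_S)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    sub_f, sub_p = freqs[mask], psd[mask]
    peak_idx = int(np.argmax(sub_p))
    reliable = bool(sub_p[peak_idx] >= min_peak_factor * max(np.median(sub_p), 1e-30))
    return float(sub_f[peak_idx]), reliable


def hrv_from_ecg(ecg: ECGRecord, rel_threshold: float = 0.3,
                 r_peaks: Optional[np.ndarray] = None) -> HRVResult:
    """Full chain: detect R peaks, build and correct the IBI series, compute
    band powers and EDR. ``r_peaks`` may be supplied (e.g. ground truth)."""
    if r_peaks is None:
        r_peaks = detect_r_peaks(ecg)
    r_peaks = np.asarray(r_peaks)
    r_peaks = r_peaks[r_peaks < ecg.signal.size]  # beat exactly at the record end
    ibi = correct_ibi(compute_ibi(r_peaks / ecg.fs), rel_threshold)
    res = hrv_band_powers(ibi)
    edr, reliable = estimate_edr(ecg, np.asarray(r_peaks, dtype=int))
    res.edr_freq = edr
    res.edr_reliable = reliable
    return res
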