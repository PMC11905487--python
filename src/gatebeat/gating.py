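"""P50 sensory-gating analysis of paired-click EEG.

Pipeline: cut epochs around the S1/S2 click markers, baseline-correct
against the [-200, -2] ms pre-stimulus window, reject any trial in which
any electrode exceeds +/-75 uV, average the retained trials, and score the
P50 component at Cz by rule: the largest strict local maximum in the
40-80 ms window, measured peak-to-preceding-trough. The S2 peak must
additionally fall within +/-10 ms of the S1 latency; if none qualifies the
S2 component is treated as completely attenuated (amplitude 0, latency set
to the S1 latency). Sensory gating is the S2/S1 amplitude ratio: 0 means
full suppression of the repeated click, values near or above 1 mean no
gating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import EEGRecording

__all__ = [
    "P50_WINDOW_MS",
    "REJECT_THRESHOLD_UV",
    "EpochSet",
    "P50Peak",
    "GatingResult",
    "UnusableSubjectError",
    "epoch_and_baseline",
    "reject_epochs",
    "average_epochs",
    "detect_p50_s1",
    "detect_p50_s2",
    "gating_ratio",
    "score_gating",
]

logger = logging.getLogger(__name__)

#: P50 scoring window at Cz, ms post-stimulus (closed).
P50_WINDOW_MS = (40.0, 80.0)
#: Artifact-rejection threshold; a trial is dropped iff some sample exceeds it.
REJECT_THRESHOLD_UV = 75.0
#: S2 peak must fall within this many ms of the S1 latency.
S2_LATENCY_TOL_MS = 10.0

_CUT_MS = (-250.0, 400.0)        # raw cut, wide enough for the baseline window
_BASELINE_MS = (-200.0, -2.0)
_ANALYSIS_MS = (-100.0, 400.0)   # reported epoch axis


class UnusableSubjectError(ValueError):
    """No scorable S1 P50; the subject's gating data cannot be used."""


@dataclass
class EpochSet:
    """Baseline-corrected trials for one condition (S1 or S2).

    ``epochs`` is trials x channels x samples in uV on the ``times_ms``
    axis; ``retained_mask`` marks trials surviving artifact rejection.
    """

    condition: str
    epochs: np.ndarray
    times_ms: np.ndarray
    ch_names: list[str]
    retained_mask: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def retained(self) -> np.ndarray:
        return self.epochs[self.retained_mask]


@dataclass
class P50Peak:
    amplitude: float   # uV, peak minus preceding trough
    latency: float     # ms
    peak_value: float  # uV, absolute voltage at the peak
    trough_value: float


@dataclass
class GatingResult:
    """Scored sensory gating for one subject/session."""

    s1_amp: float
    s2_amp: float
    s1_lat: float
    s2_lat: float
    ratio: float
    n_retained_s1: int
    n_retained_s2: int
    attenuated_s2: bool

    def __post_init__(self) -> None:
        if not (P50_WINDOW_MS[0] <= self.s1_lat <= P50_WINDOW_MS[1]):
            raise ValueError(f"S1 latency {self.s1_lat} ms outside scoring window")
        ok = abs(self.s2_lat - self.s1_lat) <= S2_LATENCY_TOL_MS or (
            self.attenuated_s2 and self.s2_lat == self.s1_lat and self.s2_amp == 0.0
        )
        if not ok:
            raise ValueError("S2 latency violates the +/-10 ms constraint")
        if self.s1_amp < 0 or self.s2_amp < 0:
            raise ValueError("amplitudes are peak-to-trough and must be >= 0")

    def to_dict(self) -> dict:
        return {
            "s1_amp_uv": self.s1_amp, "s2_amp_uv": self.s2_amp,
            "s1_lat_ms": self.s1_lat, "s2_lat_ms": self.s2_lat,
            "ratio": self.ratio,
            "n_retained_s1": self.n_retained_s1,
            "n_retained_s2": self.n_retained_s2,
            "attenuated_s2": self.attenuated_s2,
        }


def epoch_and_baseline(
    recording: EEGRecording,
    markers: pd.DataFrame,
    condition: str,
    *,
    baseline_ms: tuple[float, float] = _BASELINE_MS,
) -> EpochSet:
    """Cut and baseline-correct epochs around one condition's markers.

    Raw cuts span -250..+400 ms so the default [-200, -2] ms baseline is
    fully available; the per-channel baseline mean is subtracted and the
    epoch is reported on the -100..+400 ms analysis axis. Markers too close
    to the file edges are skipped with a log entry.
    """
    onsets = markers.loc[markers["label"] == condition, "onset_s"].to_numpy(dtype=float)
    if onsets.size == 0:
        raise ValueError(f"no markers labelled {condition!r}")
    fs = recording.fs
    lo = int(round(_CUT_MS[0] / 1000.0 * fs))
    hi = int(round(_CUT_MS[1] / 1000.0 * fs))
    cut_times = np.arange(lo, hi + 1) * 1000.0 / fs
    bmask = (cut_times >= baseline_ms[0]) & (cut_times <= baseline_ms[1])
    if not bmask.any():
        raise ValueError("baseline window empty at this sampling rate")
    amask = (cut_times >= _ANALYSIS_MS[0]) & (cut_times <= _ANALYSIS_MS[1])

    n_samp = recording.data.shape[1]
    trials = []
    skipped = 0
    for t0 in onsets:
        c = int(round(t0 * fs))
        if c + lo < 0 or c + hi + 1 > n_samp:
            skipped += 1
            continue
        cut = recording.data[:, c + lo : c + hi + 1].astype(float)
        cut = cut - cut[:, bmask].mean(axis=1, keepdims=True)
        trials.append(cut[:, amask])
    if skipped:
        logger.warning("%d %s trials skipped: too close to recording edge",
                       skipped, condition)
    if not trials:
        raise ValueError("all trials fell outside the recording")
    epochs = np.stack(trials)
    return EpochSet(
        condition=condition,
        epochs=epochs,
        times_ms=cut_times[amask],
        ch_names=list(recording.ch_names),
        retained_mask=np.ones(len(trials), dtype=bool),
    )


def reject_epochs(es: EpochSet, threshold_uv: float = REJECT_THRESHOLD_UV) -> EpochSet:
    """Drop every trial in which any electrode exceeds +/-threshold.

    The comparison is strict ("exceeded"): a trial peaking at exactly the
    threshold is retained. Raises if nothing survives.
    """
    peak = np.abs(es.epochs).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError("artifact rejection removed every trial")
    logger.info("%s: retained %d/%d trials (threshold %.0f uV)",
                es.condition, int(keep.sum()), es.n_trials, threshold_uv)
    return replace(es, retained_mask=es.retained_mask & keep)


def average_epochs(es: EpochSet) -> np.ndarray:
    """Arithmetic mean over retained trials; channels x samples."""
    if es.n_retained == 0:
        raise ValueError("no retained trials to average")
    return es.retained().mean(axis=0)


def _local_maxima(w: np.ndarray) -> np.ndarray:
    """Indices i with both full-waveform neighbours strictly lower."""
    i = np.arange(1, w.size - 1)
    return i[(w[i] > w[i - 1]) & (w[i] > w[i + 1])]


def _preceding_trough(w: np.ndarray, times_ms: np.ndarray, peak_idx: int) -> float:
    """Voltage of the most recent strict local minimum before the peak at
    t >= 0 ms; falls back to the minimum value over [0 ms, peak)."""
    i = np.arange(1, w.size - 1)
    mins = i[(w[i] < w[i - 1]) & (w[i] < w[i + 1])]
    mins = mins[(mins < peak_idx) & (times_ms[mins] >= 0.0)]
    if mins.size:
        return float(w[mins[-1]])
    pre = (times_ms >= 0.0) & (np.arange(w.size) < peak_idx)
    if not pre.any():
        return float(w[peak_idx])  # degenerate: peak at the first post-stimulus sample
    return float(w[pre].min())


def detect_p50_s1(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = P50_WINDOW_MS,
) -> Optional[P50Peak]:
    """Rule-based P50 detection on an averaged Cz waveform.

    The P50 is the largest sample in the 40-80 ms window that is a strict
    local maximum (both neighbours, taken from the full waveform, lower);
    ties break to the earliest latency. Its amplitude is the difference
    between that peak and the preceding negative trough (most recent local
    minimum at or after stimulus onset). Returns ``None`` when no sample in
    the window qualifies.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if w.shape != t.shape:
        raise ValueError("waveform and time axis must align")
    cand = _local_maxima(w)
    cand = cand[(t[cand] >= window_ms[0]) & (t[cand] <= window_ms[1])]
    if cand.size == 0:
        return None
    best = cand[int(np.argmax(w[cand]))]  # argmax returns first max -> earliest
    trough = _preceding_trough(w, t, best)
    return P50Peak(
        amplitude=float(w[best] - trough),
        latency=float(t[best]),
        peak_value=float(w[best]),
        trough_value=trough,
    )


def detect_p50_s2(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    s1_lat: float,
) -> tuple[float, float, bool]:
    """S2 P50 under the latency-consistency constraint.

    The S1 rules apply with the extra requirement that the positive peak lie
    within +/-10 ms of the S1 latency (and still inside 40-80 ms). If no
    peak qualifies the component is considered completely attenuated:
    amplitude 0, latency set to the S1 latency.

    Returns ``(amplitude_uv, latency_ms, attenuated)``.
    """
    lo = max(P50_WINDOW_MS[0], s1_lat - S2_LATENCY_TOL_MS)
    hi = min(P50_WINDOW_MS[1], s1_lat + S2_LATENCY_TOL_MS)
    peak = detect_p50_s1(waveform, times_ms, window_ms=(lo, hi))
    if peak is None:
        return 0.0, float(s1_lat), True
    return peak.amplitude, peak.latency, False


def gating_ratio(s1_amp: float, s2_amp: float) -> float:
    """S2/S1 amplitude ratio; 0 = full suppression, may exceed 1."""
    if s1_amp <= 0:
        raise UnusableSubjectError(
            "no usable S1 P50 component; subject excluded from gating analysis"
        )
    return s2_amp / s1_amp


def score_gating(
    recording: EEGRecording,
    markers: pd.DataFrame,
    *,
    scoring_channel: str = "Cz",
    threshold_uv: float = REJECT_THRESHOLD_UV,
) -> GatingResult:
    """Full paired-click scoring: epoch, reject, average, detect, ratio."""
    cz = recording.ch_names.index(scoring_channel)
    sets = {}
    for cond in ("S1", "S2"):
        es = reject_epochs(
            epoch_and_baseline(recording, markers, cond), threshold_uv
        )
        sets[cond] = es
    avg_s1 = average_epochs(sets["S1"])[cz]
    avg_s2 = average_epochs(sets["S2"])[cz]
    t = sets["S1"].times_ms

    s1 = detect_p50_s1(avg_s1, t)
    if s1 is None or s1.amplitude <= 0:
        raise UnusableSubjectError("no scorable S1 P50 at " + scoring_channel)
    s2_amp, s2_lat, attenuated = detect_p50_s2(avg_s2, sets["S2"].times_ms, s1.latency)
    return GatingResult(
        s1_amp=s1.amplitude,
        s2_amp=s2_amp,
        s1_lat=s1.latency,
        s2_lat=s2_lat,
        ratio=gating_ratio(s1.amplitude, s2_amp),
        n_retained_s1=sets["S1"].n_retained,
        n_retained_s2=sets["S2"].n_retained,
        attenuated_s2=attenuated,
    )
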