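"""Synthetic ECG/EEG sessions and cohorts with known ground truth.

Every downstream stage of the pipeline (R-peak detection, HRV spectra,
paired-click P50 scoring, resting band power, and the inference layer) is
exercised against data produced here, where the generating quantities --
LF/HF modulation amplitudes, respiration frequency, the true S2/S1 gating
ratio, and the cohort-level effect sizes -- are known exactly.

The cardiac generator is an integral pulse frequency modulation (IPFM)
model: beat times are the integer crossings of the integrated instantaneous
rate, which makes the RR spectrum analytically predictable. The paired-click
EEG generator reproduces the paradigm timing (click pairs 500 ms apart,
inter-pair gaps pseudorandomized over 8/9/10 s) with a biphasic P50-like
response at Cz whose second-click amplitude is a configurable fraction of
the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .records import ECGRecord, EEGRecording

__all__ = [
    "DEFAULT_SEED",
    "EEG_CHANNELS_32",
    "CardiacSimParams",
    "GatingSimParams",
    "CohortSpec",
    "CohortData",
    "SubjectSession",
    "ipfm_r_times",
    "synth_ecg",
    "synth_eeg_session",
    "synth_resting_eeg",
    "generate_cohort",
    "iter_cohort_sessions",
]

DEFAULT_SEED = 20231020

#: Standard 32-electrode 10-20 montage (Brain Products actiCAP layout).
EEG_CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "TP9", "TP10",
]

# Central-electrode spatial profile of the click-evoked response (relative
# to Cz, where the component is scored).
_P50_TOPOGRAPHY = {
    "Cz": 1.0, "FC1": 0.7, "FC2": 0.7, "C3": 0.6, "C4": 0.6,
    "Fz": 0.5, "CP1": 0.45, "CP2": 0.45, "Pz": 0.3,
}

_FRONTAL_CHANNELS = ["Fp1", "Fp2", "F7", "F8"]


@dataclass
class CardiacSimParams:
    """Parameters of the IPFM cardiac simulator.

    The instantaneous heart rate is
    ``mean_rate * (1 + a_lf*sin(2*pi*f_lf*t) + a_hf*sin(2*pi*f_hf*t))``
    beats/min; ``a_lf + a_hf < 1`` keeps it positive. Defaults give a 5-min
    resting recording digitized at 500 Hz with modulation at the canonical
    LF (0.10 Hz) and HF (0.25 Hz) frequencies.
    """

    mean_rate: float = 60.0          # beats/min
    a_lf: float = 0.05               # dimensionless modulation amplitude
    a_hf: float = 0.05
    f_lf: float = 0.10               # Hz
    f_hf: float = 0.25               # Hz
    resp_freq: float = 0.25          # Hz, modulates R-wave amplitude
    duration: float = 300.0          # s
    fs: float = 500.0                # Hz
    noise_sd: float = 0.0            # mV, additive white noise on the ECG
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.mean_rate <= 0:
            raise ValueError("duration and mean_rate must be positive")
        if not (0.04 <= self.f_lf < 0.15 <= self.f_hf <= 0.40):
            raise ValueError(
                "modulation frequencies must satisfy 0.04 <= f_lf < 0.15 <= f_hf <= 0.40"
            )
        if self.a_lf < 0 or self.a_hf < 0 or self.a_lf + self.a_hf >= 1:
            raise ValueError("require a_lf, a_hf >= 0 and a_lf + a_hf < 1")
        if self.fs < 250:
            raise ValueError("fs must be at least 250 Hz to resolve the QRS template")


@dataclass
class GatingSimParams:
    """Parameters of the paired-click EEG session generator."""

    n_pairs: int = 100
    intra_pair_isi: float = 0.5      # s between S1 and S2
    inter_pair_choices: tuple[float, ...] = (8.0, 9.0, 10.0)  # s
    fs: float = 512.0
    p50_s1_amp: float = 5.0          # uV, positive-peak height of the S1 response
    true_ratio: float = 0.5          # g, S2 amplitude = g * S1 amplitude
    p50_latency: float = 55.0        # ms post-click
    background_rms: float = 2.0      # uV rms, residual (post-cleaning) 1/f + alpha background
    artifact_rate: float = 0.1       # fraction of epochs given >75 uV excursions
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.true_ratio <= 1.0:
            raise ValueError("true_ratio must lie in [0, 1]")
        if not 40.0 <= self.p50_latency <= 80.0:
            raise ValueError("p50_latency must lie in the 40-80 ms scoring window")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Ground-truth structure of a simulated cohort.

    The true gating ratio of subject i is
    ``clip(base + scale*(beta_lf*z(logLF_i) + beta_edr*z(EDR_i)
    + beta_smoke*z(smoke_i) + eps_i), 0, 1)``
    with ``eps_i ~ N(0, noise_sd)``. ``scale`` maps the standardized linear
    predictor onto the physiologic [0, 1] ratio range without saturating the
    clip; signs and relative effect magnitudes are preserved.

    ``eeg_coupling`` maps ``(channel, band)`` to a correlation coefficient in
    [0, 1) linking that resting log band power to the subject's log-LF.
    """

    n_subjects: int = 31
    beta_lf: float = -0.5
    beta_edr: float = -0.4
    beta_smoke: float = -0.45
    smoker_fraction: float = 9 / 31
    noise_sd: float = 0.5
    base: float = 0.55
    scale: float = 0.25
    eeg_coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("CP1", "theta"): 0.5,
            ("Fz", "theta"): 0.5,
            ("F7", "gamma"): 0.5,
            ("FC2", "gamma"): 0.5,
            ("T8", "alpha"): 0.4,
        }
    )
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        if not 0.0 <= self.smoker_fraction <= 1.0:
            raise ValueError("smoker_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (ch, band), c in self.eeg_coupling.items():
            if not 0.0 <= c < 1.0:
                raise ValueError(f"coupling for ({ch}, {band}) must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Cardiac side
# ---------------------------------------------------------------------------

def ipfm_r_times(params: CardiacSimParams) -> np.ndarray:
    """Beat times (s) of the IPFM model.

    The cumulative beat count ``M(t) = integral_0^t r(tau) dtau`` (with r in
    beats/s) is available in closed form for sinusoidal modulation; beats are
    the times where M crosses successive integers, found by monotone
    interpolation on a dense grid. The integrator starts freshly reset at
    t = 0, so the first beat is the first threshold crossing (~one mean RR
    interval in).
    """
    r0 = params.mean_rate / 60.0  # beats/s
    dt = 1.0 / params.fs
    t = np.arange(0.0, params.duration + dt, dt)

    def _cum(t: np.ndarray) -> np.ndarray:
        out = t.copy()
        for a, f in ((params.a_lf, params.f_lf), (params.a_hf, params.f_hf)):
            if a > 0:
                out = out - a / (2 * math.pi * f) * (np.cos(2 * math.pi * f * t) - 1.0)
        return r0 * out

    m = _cum(t)
    n_beats = int(np.floor(m[-1]))
    r_times = np.interp(np.arange(1, n_beats + 1, dtype=float), m, t)
    return r_times[r_times <= params.duration]


def _qrs_template(fs: float, sigma: float = 0.008) -> np.ndarray:
    """Mexican-hat QRS-like template, unit peak, ~4*sigma half-support."""
    half = int(round(4 * sigma * fs))
    tt = np.arange(-half, half + 1) / fs
    x = tt / sigma
    return (1.0 - x**2) * np.exp(-(x**2) / 2.0)


def synth_ecg(
    r_times: np.ndarray,
    resp_freq: float = 0.25,
    fs: float = 500.0,
    *,
    r_amp: float = 1.0,
    mod_depth: float = 0.1,
    noise_sd: float = 0.0,
    duration: Optional[float] = None,
    seed: int = DEFAULT_SEED,
) -> ECGRecord:
    """Render an ECG from beat times.

    Each beat is a fixed QRS-like (mexican hat) template centred at its
    R time, with R amplitude modulated by ``1 + mod_depth*sin(2*pi*resp_freq*t)``
    -- the respiration signature that ECG-derived respiration recovers.
    Ground-truth R times are stored in ``meta["true_r_times"]``.
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size < 2 or np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing with >= 2 beats")
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    tpl = _qrs_template(fs)
    half = (tpl.size - 1) // 2
    if np.min(np.diff(r_times)) * fs < tpl.size:
        raise ValueError("beats closer than the QRS template width would overlap")

    if duration is None:
        duration = float(r_times[-1]) + 0.5
    n = int(round(duration * fs))
    sig = np.zeros(n)
    amps = r_amp * (1.0 + mod_depth * np.sin(2 * math.pi * resp_freq * r_times))
    centers = np.round(r_times * fs).astype(int)
    for c, a in zip(centers, amps):
        lo, hi = c - half, c + half + 1
        tlo, thi = max(lo, 0), min(hi, n)
        if tlo < thi:
            sig[tlo:thi] += a * tpl[tlo - lo : tpl.size - (hi - thi)]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(
        sig, fs,
        meta={"true_r_times": r_times, "resp_freq": resp_freq, "source": "synthetic"},
    )


def simulate_ecg_session(params: CardiacSimParams) -> ECGRecord:
    """IPFM beat times + waveform rendering in one call."""
    r_times = ipfm_r_times(params)
    return synth_ecg(
        r_times,
        resp_freq=params.resp_freq,
        fs=params.fs,
        noise_sd=params.noise_sd,
        duration=params.duration,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# EEG side
# ---------------------------------------------------------------------------

def _balanced_gaps(choices: tuple[float, ...], n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n inter-pair gaps, each choice appearing ~n/len(choices) times."""
    reps = int(np.ceil(n / len(choices)))
    gaps = np.tile(np.asarray(choices, dtype=float), reps)[:n]
    rng.shuffle(gaps)
    return gaps


def _pink_background(
    n_ch: int, n_samp: int, fs: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f background with an alpha (10 Hz) bump, band-limited 0.5-40 Hz."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    inband = (freqs >= 0.5) & (freqs <= 40.0)
    shape[inband] = 1.0 / np.sqrt(freqs[inband])
    # alpha bump detuned from 10 Hz: at exactly 10 Hz a stationary oscillation
    # is phase-locked to the 8/9/10 s paradigm gaps and would not average out
    shape[inband] += 0.6 * np.exp(-((freqs[inband] - 9.7) ** 2) / (2 * 1.5**2))
    spec = shape * (rng.standard_normal((n_ch, freqs.size))
                    + 1j * rng.standard_normal((n_ch, freqs.size)))
    sig = np.fft.irfft(spec, n=n_samp, axis=1)
    sig *= rms / np.std(sig, axis=1, keepdims=True)
    return sig.astype(np.float32)


def _p50_waveform(t_ms: np.ndarray, latency_ms: float, amp: float) -> np.ndarray:
    """Biphasic click response: trough ~20 ms before a positive peak.

    Difference of Gaussians, 15 ms positive-lobe width; the *positive peak*
    height equals ``amp`` so that S2/S1 peak-to-trough amplitude ratios equal
    the generating ratio exactly (identical shapes, scaled).
    """
    pos = np.exp(-((t_ms - latency_ms) ** 2) / (2 * 7.5**2))
    neg = np.exp(-((t_ms - (latency_ms - 20.0)) ** 2) / (2 * 9.0**2))
    return amp * (pos - 0.45 * neg)


def synth_eeg_session(params: GatingSimParams) -> tuple[EEGRecording, pd.DataFrame]:
    """Generate a 32-channel paired-click session and its S1/S2 markers.

    Marker timing reproduces the paradigm: ``n_pairs`` click pairs, the
    second click 500 ms after the first, inter-pair gaps drawn balanced from
    {8, 9, 10} s. Central channels carry the biphasic P50-like response with
    S2 amplitude = ``true_ratio`` x S1 amplitude. A fraction
    ``artifact_rate`` of epochs receives a 100-200 uV excursion on a frontal
    channel, placed 20-220 ms post-click so each artifact affects exactly one
    epoch (S1 and S2 cut windows overlap; a longer excursion would bleed into
    the neighbouring epoch and distort the per-condition retention count).
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    gaps = _balanced_gaps(params.inter_pair_choices, params.n_pairs - 1, rng)
    s1_times = 2.0 + np.concatenate([[0.0], np.cumsum(gaps)])
    s2_times = s1_times + params.intra_pair_isi
    duration = s2_times[-1] + 2.0
    n_samp = int(round(duration * fs))
    n_ch = len(EEG_CHANNELS_32)

    data = (
        _pink_background(n_ch, n_samp, fs, params.background_rms, rng)
        if params.background_rms > 0
        else np.zeros((n_ch, n_samp), dtype=np.float32)
    )

    # evoked response template on a 0-400 ms grid
    tpl_t = np.arange(0, int(round(0.4 * fs))) * 1000.0 / fs
    tpl_s1 = _p50_waveform(tpl_t, params.p50_latency, params.p50_s1_amp)
    tpl_s2 = tpl_s1 * params.true_ratio
    topo = np.array([_P50_TOPOGRAPHY.get(ch, 0.0) for ch in EEG_CHANNELS_32])

    for times, tpl in ((s1_times, tpl_s1), (s2_times, tpl_s2)):
        for t0 in times:
            i0 = int(round(t0 * fs))
            data[:, i0 : i0 + tpl.size] += (topo[:, None] * tpl[None, :]).astype(
                np.float32
            )

    # artifacts: independent Bernoulli per epoch, one frontal channel each
    all_marks = np.concatenate([s1_times, s2_times])
    hit = rng.random(all_marks.size) < params.artifact_rate
    art_len = int(round(0.2 * fs))
    art_shape = np.sin(np.linspace(0, math.pi, art_len)) ** 2
    for t0 in all_marks[hit]:
        ch = rng.integers(len(_FRONTAL_CHANNELS))
        ch_idx = EEG_CHANNELS_32.index(_FRONTAL_CHANNELS[ch])
        amp = rng.uniform(120.0, 200.0) * rng.choice([-1.0, 1.0])
        i0 = int(round((t0 + 0.02) * fs))
        data[ch_idx, i0 : i0 + art_len] += (amp * art_shape).astype(np.float32)

    markers = pd.DataFrame(
        {
            "onset_s": np.concatenate([s1_times, s2_times]),
            "label": ["S1"] * params.n_pairs + ["S2"] * params.n_pairs,
        }
    ).sort_values("onset_s", ignore_index=True)

    rec = EEGRecording(
        data, fs, list(EEG_CHANNELS_32),
        meta={
            "true_ratio": params.true_ratio,
            "p50_latency": params.p50_latency,
            "n_artifact_epochs": int(hit.sum()),
            "source": "synthetic",
        },
    )
    return rec, markers


def synth_resting_eeg(
    log_band_powers: pd.DataFrame,
    duration: float = 300.0,
    fs: float = 512.0,
    band_edges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = DEFAULT_SEED,
) -> EEGRecording:
    """Resting EEG whose per-channel band powers realize given targets.

    ``log_band_powers`` is channels x bands, ln(uV^2). Each band is rendered
    as band-limited Gaussian noise (flat within its edges, random phases)
    scaled so that its variance equals ``exp(log power)``; Welch estimates of
    band power then match the targets up to spectral-estimation error.
    """
    from .spectra import DEFAULT_BANDS  # local import to avoid cycle

    edges = band_edges or DEFAULT_BANDS
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    ch_names = list(log_band_powers.index)
    data = np.zeros((len(ch_names), n_samp), dtype=np.float32)
    for j, band in enumerate(log_band_powers.columns):
        lo, hi = edges[band]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            continue
        spec = np.zeros((len(ch_names), freqs.size), dtype=complex)
        spec[:, mask] = rng.standard_normal((len(ch_names), mask.sum())) + 1j * rng.standard_normal(
            (len(ch_names), mask.sum())
        )
        comp = np.fft.irfft(spec, n=n_samp, axis=1)
        target_sd = np.sqrt(np.exp(log_band_powers.iloc[:, j].to_numpy(dtype=float)))
        comp *= (target_sd / np.std(comp, axis=1))[:, None]
        data += comp.astype(np.float32)
    return EEGRecording(data, fs, ch_names, meta={"source": "synthetic"})


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectSession:
    """Full-physics raw data for one simulated subject."""

    subject: str
    ecg: ECGRecord
    eeg_gating: EEGRecording
    markers: pd.DataFrame
    eeg_rest: EEGRecording


@dataclass
class CohortData:
    """A simulated cohort: feature/ground-truth table plus, in full-physics
    mode, a lazy per-subject session iterator."""

    table: pd.DataFrame
    sessions: Optional[Iterator[SubjectSession]] = None


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _latents(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject latent physiology and the true gating ratio.

    Latent scales follow resting young-adult norms: ln LF around 7.4 ln(ms^2)
    (median LF log 7.47 in comparable cohorts), ln HF around 6.0, respiration
    0.27 +/- 0.05 Hz.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    z_lf = rng.standard_normal(n)
    log_lf = 7.4 + 0.7 * z_lf
    log_hf = 6.0 + 0.6 * (0.5 * z_lf + math.sqrt(0.75) * rng.standard_normal(n))
    edr = np.clip(0.27 + 0.05 * rng.standard_normal(n), 0.13, 0.43)
    smoke = (rng.random(n) < spec.smoker_fraction).astype(int)
    linpred = (
        spec.beta_lf * _zscore(log_lf)
        + spec.beta_edr * _zscore(edr)
        + spec.beta_smoke * _zscore(smoke.astype(float))
        + rng.normal(0.0, spec.noise_sd, n)
    )
    g = np.clip(spec.base + spec.scale * linpred, 0.0, 1.0)

    df = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:03d}" for i in range(n)],
            "true_log_lf": log_lf,
            "true_log_hf": log_hf,
            "true_edr_hz": edr,
            "smoker": smoke,
            "true_ratio": g,
        }
    )
    return df


def _band_power_features(
    spec: CohortSpec, z_lf: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """160 log band powers (32 ch x 5 bands); coupled features correlate
    with log-LF at the configured coefficient."""
    from .spectra import DEFAULT_BANDS

    # typical resting log power (ln uV^2) per band
    band_mu = {"delta": 3.5, "theta": 2.8, "alpha": 3.2, "beta": 1.8, "gamma": 0.7}
    band_sd = 0.6
    n = z_lf.size
    cols: dict[str, np.ndarray] = {}
    for ch in EEG_CHANNELS_32:
        for band in DEFAULT_BANDS:
            c = spec.eeg_coupling.get((ch, band), 0.0)
            eps = rng.standard_normal(n)
            cols[f"{ch}_{band}"] = band_mu[band] + band_sd * (
                c * z_lf + math.sqrt(1.0 - c**2) * eps
            )
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec, mode: str = "table") -> CohortData:
    """Simulate a cohort with known ground truth.

    In ``"table"`` mode the per-subject feature table (observed HRV logs,
    EDR, gating amplitudes/ratio, 160 resting log band powers) is emitted
    directly, with small measurement noise on top of the latents. In
    ``"full"`` mode the same table is returned together with a lazy iterator
    of raw sessions (ECG, paired-click EEG, resting EEG) simulated from the
    same latents; ground-truth columns are identical across modes for the
    same seed.
    """
    if mode not in ("table", "full"):
        raise ValueError("mode must be 'table' or 'full'")
    lat = _latents(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]).generate_state(1)[0])

    feats = _band_power_features(spec, _zscore(lat["true_log_lf"].to_numpy()), rng)

    # observed (measured) quantities: latent + small measurement noise
    n = spec.n_subjects
    tab = lat.copy()
    tab["log_lf"] = lat["true_log_lf"] + rng.normal(0, 0.05, n)
    tab["log_hf"] = lat["true_log_hf"] + rng.normal(0, 0.05, n)
    tab["edr_hz"] = np.clip(lat["true_edr_hz"] + rng.normal(0, 0.005, n), 0.1, 0.5)
    s1 = np.clip(rng.normal(5.0, 1.0, n), 2.0, None)
    s2 = np.clip(lat["true_ratio"] * s1 + rng.normal(0, 0.15, n), 0.0, None)
    tab["s1_amp"] = s1
    tab["s2_amp"] = s2
    tab["ratio"] = s2 / s1
    table = pd.concat([tab, feats], axis=1)

    sessions = iter_cohort_sessions(spec, table) if mode == "full" else None
    return CohortData(table=table, sessions=sessions)


def iter_cohort_sessions(
    spec: CohortSpec,
    table: pd.DataFrame,
    *,
    ecg_duration: float = 300.0,
    rest_duration: float = 120.0,
    n_pairs: int = 100,
    artifact_rate: float = 0.1,
    background_rms: float = 2.0,
) -> Iterator[SubjectSession]:
    """Yield one full-physics session per subject, lazily (a session is
    tens of MB; the cohort is never materialized at once).

    The subject's latent ln LF/HF set the IPFM modulation amplitudes via
    LF power ~= (T0 * a_lf)^2 / 2 for mean RR interval T0, so the pipeline's
    spectral estimates are monotone in the latents.
    """
    from .spectra import DEFAULT_BANDS

    ss = np.random.SeedSequence([spec.seed, 2])
    children = ss.spawn(len(table))
    for (idx, row), child in zip(table.iterrows(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        mean_rate = 62.0
        t0_ms = 60000.0 / mean_rate
        a_lf = math.sqrt(2.0 * math.exp(row["true_log_lf"])) / t0_ms
        a_hf = math.sqrt(2.0 * math.exp(row["true_log_hf"])) / t0_ms
        total = a_lf + a_hf
        if total >= 0.9:  # keep instantaneous rate safely positive
            a_lf, a_hf = 0.9 * a_lf / total, 0.9 * a_hf / total
        cparams = CardiacSimParams(
            mean_rate=mean_rate,
            a_lf=a_lf,
            a_hf=a_hf,
            resp_freq=float(row["true_edr_hz"]),
            duration=ecg_duration,
            noise_sd=0.02,
            seed=sub_seed,
        )
        ecg = simulate_ecg_session(cparams)

        gparams = GatingSimParams(
            n_pairs=n_pairs,
            true_ratio=float(row["true_ratio"]),
            artifact_rate=artifact_rate,
            background_rms=background_rms,
            seed=sub_seed + 1,
        )
        eeg_gating, markers = synth_eeg_session(gparams)

        band_cols = [f"{ch}_{band}" for ch in EEG_CHANNELS_32 for band in DEFAULT_BANDS]
        log_bp = pd.DataFrame(
            row[band_cols].to_numpy(dtype=float).reshape(len(EEG_CHANNELS_32), -1),
            index=EEG_CHANNELS_32,
            columns=list(DEFAULT_BANDS),
        )
        eeg_rest = synth_resting_eeg(log_bp, duration=rest_duration, seed=sub_seed + 2)

        yield SubjectSession(
            subject=str(row["subject"]),
            ecg=ecg,
            eeg_gating=eeg_gating,
            markers=markers,
            eeg_rest=eeg_rest,
        )
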