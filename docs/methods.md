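# Methods

This note documents the models, estimators, and numerical choices behind
gatebeat, what the synthetic-data generator does and does not emulate, and
the problem sizes used by the test suite and the acceptance script.

## Cardiac simulation (IPFM)

Beat times follow the integral pulse frequency modulation model: with
instantaneous rate r(t) = r₀·(1 + a_LF sin 2πf_LF t + a_HF sin 2πf_HF t)
(r₀ in beats/s), a beat fires whenever ∫₀ᵗ r(τ)dτ crosses an integer. The
integral is available in closed form for sinusoidal modulation, and the
crossings are found by monotone interpolation on a 1/fs grid, so beat
times are accurate to well below a sample. For small modulation depths
the RR series is approximately T₀·(1 − a sin 2πft), giving the analytic
check used throughout: an RR modulation of amplitude A ms contributes
A²/2 ms² of band power at f. Constraints: a_LF + a_HF < 1 keeps the rate
positive; 0.04 ≤ f_LF < 0.15 ≤ f_HF ≤ 0.40 keeps each modulation in its
nominal band.

The ECG waveform renders each beat as a mexican-hat QRS template (σ = 8 ms)
with R amplitude scaled by 1 + 0.1·sin(2πf_resp t) — the respiratory
amplitude modulation that EDR estimation exploits. Additive white noise is
optional. The first beat is the first integrator crossing (~one RR in), so
every rendered template has full support and ground truth aligns with
detectable peaks.

## HRV estimation

- **R detection**: band-pass 5–25 Hz, derivative–square–integrate
  (150 ms window), adaptive threshold at 20% of the 99th percentile,
  200 ms refractory period, peak refinement on the band-passed signal.
- **IBI correction**: intervals deviating >30% (relative) from an
  11-point running median are replaced by a cubic spline through the
  clean intervals; >20% flagged intervals raises a quality error rather
  than silently producing an unusable spectrum.
- **Spectra**: cubic interpolation of the tachogram to 4 Hz, linear
  detrend, Welch PSD (120 s Hann segments, 50% overlap). Band powers are
  rectangle-integrated with a half-open LF band [0.04, 0.15) so the
  0.15 Hz bin is never counted twice. Logs are natural: resting LF powers
  around e^7.4 ≈ 1600 ms² are physiologic, which a base-10 convention
  would not be.
- **EDR**: the R-peak amplitude series, resampled and detrended the same
  way; the estimate is the PSD argmax in 0.10–0.50 Hz. If the peak is
  less than 5× the median in-band density the estimate is flagged
  unreliable (no clear respiratory modulation) but still returned.

With 120 s Welch segments the frequency resolution is 1/120 Hz ≈ 0.008 Hz,
comfortably inside the ±0.02 Hz EDR acceptance band.

## Paired-click simulation and P50 scoring

Markers reproduce the paradigm: pairs 500 ms apart, inter-pair onsets
drawn *balanced* from {8, 9, 10} s (each gap ≈ n/3 times, shuffled) —
pseudorandomization with lower variance than i.i.d. draws. The evoked
response is a difference of Gaussians: positive lobe at the configured
latency (default 55 ms, σ = 7.5 ms), negative lobe 20 ms earlier
(σ = 9 ms, 45% amplitude), giving a clear trough-then-peak shape. The S2
response is the S1 template scaled by the true ratio g, so peak-to-trough
amplitude ratios equal g exactly in the absence of noise. The response
appears at Cz at full amplitude and at neighbouring central electrodes
scaled down.

**Background.** Channels carry independent 1/f noise with an alpha bump,
band-limited 0.5–40 Hz, default 2 µV rms. Two deliberate choices:

- The background represents *residual* EEG after the visual screening and
  ICA cleanup that a recording pipeline applies before epoching (that
  cleanup itself is out of scope here); raw-scalp amplitudes would be
  several times larger. At 2 µV rms and ~90 retained trials the residual
  noise in the average is ≈0.2 µV, which keeps the peak-to-trough ratio
  estimator's selection bias within the ±0.15 recovery band the package
  commits to.
- The alpha bump sits at 9.7 Hz, not 10 Hz. A *stationary* oscillation at
  exactly 10 Hz is phase-locked to the integer-second paradigm gaps and
  would never average out across trials — an artifact of the linear
  background model, not of real alpha, whose coherence time is far
  shorter than the inter-pair interval.

**Artifacts** are 120–200 µV, 200 ms raised-sine excursions on a random
frontal channel, placed 20–220 ms after a marker. Each epoch receives one
independently with probability `artifact_rate`, and the placement keeps
the excursion inside exactly one epoch's cut window (S1/S2 cuts overlap;
longer or earlier excursions would contaminate the neighbouring epoch and
distort per-condition retention counts). They are guaranteed to trip the
±75 µV rule and nothing else is.

**Scoring rules.** Epochs are cut −250…+400 ms so the [−200, −2] ms
baseline is fully available, and reported on a −100…+400 ms axis.
Rejection is strict (> 75 µV drops; exactly 75 µV is retained) and applied
after baseline correction. The P50 is the largest sample in the *closed*
40–80 ms window that is a strict local maximum with neighbours taken from
the full waveform (so window endpoints are eligible); ties break to the
earliest latency. The trough is the most recent strict local minimum
before the peak at ≥0 ms, falling back to the minimum value between
stimulus onset and the peak — pre-stimulus dips are baseline noise, not
component structure. The S2 window is the intersection of 40–80 ms with
S1 latency ±10 ms; an empty result means a fully attenuated S2 (amplitude
0, latency pinned to S1). A subject without a scorable S1 peak is
unusable for gating and excluded from all analyses.

## Resting spectra

Welch with 4 s Hann segments, 50% overlap; bands delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–40 Hz (clinical convention truncated at
the 40 Hz acquisition filter; configurable). Band powers are absolute
(µV²) with natural logs; the Boruta feature matrix is all 32 channels ×
5 bands = 160 log powers.

## Cohort model

Per subject: ln LF ~ N(7.4, 0.7²) ln(ms²), ln HF ~ N(6.0, 0.6²) with 0.5
correlation to ln LF, respiration ~ N(0.27, 0.05²) Hz (clipped to
0.13–0.43), smoking ~ Bernoulli(9/31). The true gating ratio is

    g = clip(0.55 + 0.25·(β_LF·z(lnLF) + β_EDR·z(EDR) + β_smoke·z(smoke) + ε), 0, 1),

ε ~ N(0, 0.5). The 0.25 scale maps the standardized linear predictor onto
the physiologic [0, 1] ratio range without saturating the clip; because
all drivers enter z-scored, the recoverable standardized regression
coefficients approximate the configured betas (shrunk a few percent by
clipping and measurement noise). Default betas (−0.5, −0.4, −0.45) give
R² ≈ 0.64.

In *table* mode the generator emits observed features directly (latents
plus small measurement noise). In *full-physics* mode the same latents
drive per-subject raw sessions: the IPFM amplitudes are set from the
latent powers via a = √(2·e^lnP)/T₀, respiration sets both the R-amplitude
modulation and the EDR target, the gating session uses the subject's true
g, and the resting EEG is synthesized so that its Welch band powers
realize the latent log powers (band-limited noise with matched variance;
coupled channels correlate with ln LF at the configured coefficient).
Both modes share the latent draw, so ground-truth columns are identical
for the same seed; sessions are yielded lazily because one session is
tens of MB.

What the generator does **not** emulate: realistic ECG morphology (P/T
waves), nonstationary or spatially correlated EEG backgrounds, ocular
physiology, volume conduction, or non-sinusoidal HRV dynamics. Passing
tests therefore demonstrate correctness of the measurement and inference
chain under a known generative model, not robustness to every real-world
recording pathology.

## Inference

- **Spearman**: Pearson correlation of midranks; p from the t
  approximation with n−2 df (an exact permutation option exists for tiny
  samples).
- **Bootstrap**: 1000 paired resamples, percentile interval; degenerate
  resamples (zero variance after resampling) are skipped and logged.
  Deterministic given a seed.
- **FDR**: Benjamini–Hochberg step-up, applied across the whole
  correlation family (4 autonomic measures × 3 gating outcomes). Note the
  step-up adjustment is not idempotent; reapplying it can only increase
  values.
- **Standardized regression**: predictors and outcome z-scored (ddof 1),
  OLS with intercept, two-sided t-tests; rank-deficient designs raise an
  error naming the collinear columns.
- **Boruta**: per iteration, every in-model feature gets one shuffled
  shadow copy; a 500-tree random-forest regressor (max_features √p) is
  fitted and a feature scores a hit when its importance exceeds the best
  shadow's. Hit counts are tested against Binomial(n, ½) two-sided at
  α = 0.01 with a Bonferroni adjustment across the feature count — without
  it, sequential testing over many features confirms pure-noise features
  at an unacceptable rate (a chance in-sample correlation persists every
  iteration, while shadows are re-permuted). Importances are the forest's
  impurity-based scores; out-of-model permutation importances are
  available via `importance="permutation"` at a substantial runtime cost.
  Rejected features leave the model; features undecided after `max_iter`
  (default 100) are tentative and treated as not important. The five-seed
  consensus keeps only features confirmed under every seed — an empty
  consensus is an expected outcome for weakly coupled targets.

## Reproducibility and problem sizes

A single master seed fans out to per-stage seeds through
`numpy.random.SeedSequence` spawning, so every report is byte-identical
under a fixed config. The test suite and `scripts/acceptance.py` scale
replicate counts to desk-size runs: 12 seeded sessions per gating ratio,
two master seeds per Boruta condition (five RF seeds each), four
full-physics cohorts of n = 31 with 50 click pairs and 60 s resting EEG
per subject, 500 bootstrap-coverage replicates. Tolerances are those the
estimators are designed to meet (LF power within 15% of the analytic
value, EDR within ±0.02 Hz, gating ratio within 0.15 in ≥90% of runs,
CI coverage 90–98%, exact agreement for the rule-based and rank-based
oracles); replicate counts affect only the sharpness of those checks,
never the thresholds.

## Known limitations

- The P50 peak-to-trough estimator is biased upward at low signal-to-noise
  (max-selection over a window); the package controls this via trial
  counts and the residual-noise operating point rather than by smoothing,
  which would alter latencies.
- Kubios-style smoothness-priors detrending is not replicated; exact
  numeric agreement with analyses done in that software is not expected
  even on identical recordings.
- EDF export is 16-bit with per-channel physical scaling (quantization
  ≈ range/65535); BrainVision files are read, not written.
- Boruta results at n ≈ 31 are conservative: with Bonferroni-adjusted
  binomial tests across 160 features, weak couplings often end tentative,
  and the all-seeds consensus can be empty.
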