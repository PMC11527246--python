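# Methods

This note documents the models and procedures implemented in `esgpipe`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Signal model and preprocessing chain

A recording is a channels × samples array in microvolts with a sampling
rate, channel metadata (role: esg/eeg/ecg/eng, patch, grid position in
cm) and stimulus events at 0-based sample indices. The pipeline runs:

1. **Stimulation-artifact interpolation.** Electrical nerve stimulation
   leaves a brief transient on every channel. The artifact window is
   found on the grand mean over trials and patch channels: the sample of
   maximum absolute deviation from the pre-stimulus baseline mean seeds
   the window if it exceeds k = 8 baseline SDs, and the window expands
   outwards until the deviation re-enters max(1 SD, 2 % of the peak
   deviation), plus a 0.5 ms guard band per side. The relative-exit term
   is essential: the baseline SD of a grand average is σ/√(N·C), far
   below the evoked amplitude, so a pure SD re-entry criterion walks out
   of the transient and into the evoked response. Detected (or manually
   overridden) windows are replaced by shape-preserving piecewise cubic
   Hermite (PCHIP) interpolation anchored on 5 context samples per side;
   samples outside windows are bit-identical to the input. With no
   suprathreshold transient a flagged default window of (−1, +4) ms is
   used.
2. **Resampling** to 1 kHz by polyphase filtering (anti-alias included);
   event indices are rescaled.
3. **Cardiac artifact removal** (below), on the ESG channels, before
   band-pass filtering so the broadband artifact shape is fit intact.
4. **Re-referencing.** Channel or average reference. Subtracting a
   ventral channel cancels the recording reference's own noise (common
   to all channels referenced against it) and, for a radial
   dorso-ventral dipole, adds the opposite pole to the dorsal grid.
   The previous reference can be retained as an explicit channel so the
   operation is invertible.
5. **Zero-phase filtering.** Forward–backward fourth-order Butterworth
   band-pass (default 30–400 Hz) and band-stop (48–53 Hz), i.e.
   effective order 8 and squared magnitude: the two-pass gain at a band
   edge is (1/√2)² = 0.5. The 50 Hz comb option is a cascade of
   second-order notch sections at harmonics k·50 Hz with −3 dB bandwidth
   0.003·(fs/2), applied forward–backward.
6. **Sample rejection.** Per-role absolute thresholds (default: ESG
   100 µV), optionally on band-filtered copies with SD multipliers
   (for EEG-style rules); a channel with more than 50 % flagged samples
   is dropped instead of contributing to the keep-mask.
7. **Epoching.** Inclusive millisecond endpoints (−200..700 ms at 1 kHz
   = 901 samples); per-trial per-channel baseline mean (−110..−10 ms)
   subtracted; trials overlapping rejected samples are retained in the
   array but flagged out of every average and training set.

## Cardiac artifact removal (optimal basis set)

R-peaks are detected on the ECG channel from a band-passed (8–40 Hz),
squared and smoothed energy envelope with a 300 ms refractory period,
each detection refined to the largest raw deflection within ±50 ms;
curated annotations can be supplied verbatim. Per ESG channel, all
complete beat windows (−⌊0.5·median RR⌋ .. +⌊0.5·median RR⌋ samples,
window length 2·⌊0.5·RR⌋+1) form an artifact × time matrix. The basis
is the mean artifact plus the first four principal components of the
matrix *after* removing the mean (centering makes "mean + PCs" a
non-redundant basis; with uncentred PCA the first component would
largely duplicate the mean). Each beat's segment — clipped at the
midpoints between adjacent R-peaks and at the recording bounds — is fit
by ordinary least squares on the basis and the fit subtracted. The fit
is a projection, so a second pass with the same basis changes
essentially nothing, and samples outside all beat windows are untouched.

Two properties matter for interpretation. First, the basis is estimated
from noisy segments, so at low artifact-to-noise ratios the PCs carry
estimation noise and the achievable residual is noise-limited — the
80 %+ reduction the suite demonstrates presumes the severe artifacts
(~100 µV against ~6 µV background) typical of these recordings. Second,
because beat windows tile most of the recording, heartbeat-locked
residual leaks into a stimulus-locked average as ~1/√N noise; efficacy
is therefore quantified at a study-scale trial count (1000).

## CCAR spatial filtering

X concatenates the retained single-trial windows (channels × N·w); Y is
the trial average tiled N times. Training uses an 11-sample window
(±5 ms at 1 kHz) around the expected component latency. The canonical
directions maximizing corr(w_xᵀX, w_yᵀY) are obtained by eigendecomposing
Cxx and Cyy with ridge ε·trace/dim (ε = 1e−6; 0 allowed for full-rank
data), whitening, and an SVD of the whitened cross-covariance;
eigendirections below numerical rank are dropped, so with rank-deficient
data the component count equals the numerical rank. Activation patterns
are Cov(X)·W_x. A warning is emitted when training columns fall below
50 × channels (sample-to-feature guard).

**Component selection.** Among the first two components (configurable),
a component qualifies when the filtered trial average peaks within a
latency tolerance (default ±3 ms) of the expected latency and — when a
target electrode is named — its activation pattern couples positively
into the target after sign normalization, i.e. the sensor over the
expected dipole pole deflects with the component's polarity. The filter
sign is set so the average peak has the expected polarity (negative for
the cervical N13); ties break toward the higher-correlation component.
Selection failure raises with per-component diagnostics rather than
guessing.

**Transfer.** Filters trained on high-SNR mixed-nerve epochs are applied
unchanged (same weights, same sign) to sensory-nerve epochs; the suite
verifies that a 2/3 planted amplitude ratio is recovered within 0.05.

**Stability control.** Training CCA on random 50 % subsamples of trials
(1000 repetitions in the full protocol; fewer in the suite) and
correlating the first-component time-courses inside the training window
yields near-unity mean |r| when a repeated evoked response is present
and substantially lower values on resting surrogates with identical
trial timings; a one-tailed paired t test across participants compares
the two.

## Metrics

Peak latency and amplitude are read at the extremum of expected polarity
inside a search window of the trial average. If the extremum magnitude
falls below 2 baseline SDs (detection_k, a stand-in for the visual
inspection used in practice), the measure is flagged not visible and the
amplitude is read at a supplied group-average latency. SNR is
RMS(±1 ms around the peak) / RMS(a same-length pre-stimulus window),
mirrored at −latency by default (a window ending at −10 ms is the
alternative, since the placement "the same window before stimulus onset"
is ambiguous). Note the estimator's variance: at 1 kHz the ±1 ms window
holds 3 samples, so single SNR estimates scatter by tens of percent;
comparisons in the suite therefore widen the window (the halfwidth is an
argument) or average over seeds. Time-frequency maps use a hop-1
short-time FFT with a 21 ms Hann window zero-padded to 1024 points, each
frequency row divided by its mean over the −200..−10 ms baseline.

## Statistics

One-sample and paired t tests report t, p (two-sided by default,
one-sided available), the two-sided 95 % CI of the mean, and Cohen's
d = mean/SD. Identical paired inputs return a degenerate null result
(t = 0, p = 1, flagged) instead of an error. The interaction ratio
IR = 100·((D1+D2) − D1D2)/(D1+D2) quantifies two-digit integration
(0 % additivity, positive attenuation, negative amplification) and is
scale-invariant.

The cluster-based permutation test compares paired conditions
(participants × channels × time): per-sample paired t, two-sided
cluster-forming threshold at α_cluster = 0.05, clusters of equal-sign
suprathreshold samples connected through channel adjacency (grid
channels within 2.5 cm, capturing 1 and 2 cm neighbours and isolating
the 5 cm columns) or consecutive samples, scored by summed t. The null
is the max-cluster-mass distribution over per-participant sign flips of
the differences — enumerated exactly when 2ⁿ ≤ 4096, otherwise 1000
seeded random flips including the identity. Positive and negative
clusters are formed separately and both reported; cluster p values
receive no further correction. The per-permutation t maps reuse the
flip-invariant per-sample sum of squares, and max masses are computed by
a union-find kernel (numba-compiled when available, with an equivalent
scipy connected-components fallback) — 500 null calibrations at n = 12
with exact 4096-flip enumeration run in about a minute.

Power: the power of a one-sample t test at effect size d is computed
from the noncentral t (ncp = |d|·√n); the minimal n meets a target power
by direct search. The preregistration-style defaults (one-tailed,
α = 0.05, power 0.90) give n = 36 at d = 0.5 and n = 24 at d = 0.62.

## Robustness curves

Single-trial peak amplitudes (extracted at the average-trace latency,
filters trained once on all trials — never retrained per resample) feed
two Monte-Carlo analyses: per participant, k trials resampled with
replacement and tested against zero (k over a 5..1000-step-10 grid by
default, 1000 repetitions); at group level, participants are resampled
with replacement first, then trials within each resampled occurrence
independently, trial means averaged per participant and tested across
participants. Two caveats are inherent to the resampling scheme: the
test is calibrated at the nominal α only when the resample size is small
relative to the trial pool (resampling a pool's own size tests the
pool's fixed sample mean), and curves are non-decreasing only up to
Monte-Carlo jitter. Two-sided testing is the default; one-sided is
exposed for signed hypotheses.

## The synthetic generator

`generate_recording` plants, on the 17-electrode grid plus a ventral
channel and an ECG channel:

- a dipolar evoked source: unit-norm Gaussian spatial pattern
  exp(−d²/2s²) around a centre (default the grid target, scale 2 cm),
  rescaled so the best electrode carries the nominal peak amplitude; a
  triphasic temporal template (small early positive, main negative, slow
  late positive lobe — a difference of Gaussians normalized to −1);
  per-trial amplitudes with a truncated-normal coefficient of variation;
  an opposite pole (gain 0.5) on the ventral channel;
- cardiac artifacts at R-peaks drawn from a truncated normal RR
  (minimum 300 ms): a QRS+T-like waveform with per-channel gains
  (default peak 100 µV — "severe" relative to ~6 µV background), rank-1
  beat-to-beat shape variability along the waveform's derivative (so the
  4-PC OBS provably spans it), and an optional higher-rank stress axis;
  a matching high-amplitude ECG trace;
- brief stimulation transients (Hann pulse, default 400 µV over
  −0.5..3 ms) on all channels;
- noise: white (5 µV), spectrally shaped 1/f^β (3 µV, β = 1), fixed-phase
  50 Hz line noise with harmonics at −20 dB each, and common
  reference-electrode noise (5 µV) added identically to every channel
  recorded against the spinal reference — the component a
  re-reference cancels.

Stimulus trains use the study-protocol defaults (10 kHz sampling, 2000
stimuli, 763 ms inter-stimulus interval with ±50 ms uniform jitter in
1 ms steps); consecutive epochs may then overlap, as in the emulated
protocol, and a warning says so. `generate_resting_state` consumes the
random stream identically and omits only the evoked source and
transients, so a same-seed task/rest pair shares its noise and cardiac
realization exactly — paired subtraction isolates the planted evoked
contribution, which the tests use as a ground-truth oracle. All outputs
are deterministic in the seed. Ground truth (event samples, R-peak
samples, noiseless evoked template, pattern, trial amplitudes)
round-trips through a TSV/JSON sidecar.

What the generator does **not** emulate: volume-conduction forward
physics, realistic ECG morphology beyond the parameterized template,
spatially correlated background (noise is independent across channels
apart from the common reference term), muscle/ocular artifacts,
respiration, electrode drift or impedance changes. Passing tests
therefore demonstrate correctness of the algorithms under a controlled
signal model, not field performance on arbitrary recordings.

## Problem sizes in the test suite

Tests and the acceptance script run at 1 kHz (the analysis rate) with
hundreds to a thousand trials rather than the full 10 kHz / 2000-trial
protocol; these sizes are chosen so that every qualitative property
(artifact containment, pattern recovery, calibration, SNR gain) is
preserved while a complete run stays desk-scale. Where an estimator's
own variance would otherwise dominate a comparison (the 3-sample SNR
window, the finite-average cardiac leak), the affected check states and
uses the stabilized variant (wider RMS window, study-scale trial count).

## Known limitations

- Automatic stimulation-artifact detection approximates a manual/visual
  procedure; detected windows carry a flag when the fallback was used,
  and manual overrides are first-class.
- The EEG-specific cleanup path (ICA-based ocular/muscle removal) is a
  pluggable hook, not implemented here; `interpolate_channels` is an
  inverse-distance convenience, not a spherical spline.
- BIDS support is a directory-layout convention over the BrainVision
  reader, not a validator.
- Whether rejection thresholds apply before or after re-referencing is
  not standardized; this pipeline applies them after.
- The signal-space-projection alternative for cardiac cleanup is
  documented but not implemented.
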