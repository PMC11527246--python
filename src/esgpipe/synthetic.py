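"""Synthetic multichannel grid recordings with known ground truth.

The generator emulates an electrospinography stimulation block: a dipolar
evoked response planted on the 17-electrode spinal grid (with an opposite
pole on a ventral channel), cardiac artifacts time-locked to R-peaks with
RR variability and rank-1 shape variability, brief high-amplitude
stimulation transients, white + 1/f + 50 Hz line noise, and a stimulus
train with uniform inter-stimulus-interval jitter.  Default conditions
mirror the mixed-nerve study protocol: 10 kHz sampling, 2000 stimuli at a
763 ms interval jittered by ±50 ms in 1 ms steps, and a cervical N13-like
response (negative peak near 13 ms, ~1.4 µV against a ventral reference).

A matched resting-state surrogate reuses the identical noise and cardiac
realization (same seed) with the evoked source and stimulation transients
switched off, so task − rest isolates the planted response exactly.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_montage import ChannelInfo, MontageSpec, Recording, builtin_montage

__all__ = [
    "SourceSpec",
    "CardiacSpec",
    "NoiseSpec",
    "StimArtifactSpec",
    "SimulationConfig",
    "SimTruth",
    "dipole_pattern",
    "default_cardiac_template",
    "generate_recording",
    "generate_resting_state",
    "write_truth",
    "load_truth",
]

STIM_CODE = "Stimulus/S  1"


@dataclass
class SourceSpec:
    """Planted dipolar evoked source.

    ``pattern`` holds unit-norm per-electrode weights of a radial dipole
    (the stored direction); for signal generation the pattern is rescaled
    so its largest weight is 1, making ``amplitude_uv`` the magnitude of
    the main (negative) peak at the best electrode.  ``amplitude_cv`` is
    the trial-to-trial coefficient of variation and ``ventral_gain``
    scales the opposite pole planted on the ventral channel.
    """

    pattern: np.ndarray
    latency_ms: float = 13.3
    width_ms: float = 2.5
    amplitude_uv: float = 1.4
    amplitude_cv: float = 0.3
    ventral_gain: float = 0.5

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        nrm = np.linalg.norm(self.pattern)
        if nrm == 0:
            raise ValueError("source pattern must not be all zeros")
        self.pattern = self.pattern / nrm
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")


@dataclass
class CardiacSpec:
    """Cardiac artifact generator: RR statistics and per-channel waveform.

    ``template`` is a channels × window waveform in µV centred on the
    R-peak; ``variation_axis`` (same shape) spans the single direction of
    beat-to-beat shape variability, scaled per beat by a standard-normal
    draw times ``pc_jitter``.  ``rank2_axis`` enables a higher-rank stress
    mode when set.
    """

    rr_mean_ms: float = 850.0
    rr_sd_ms: float = 50.0
    template: np.ndarray | None = None
    variation_axis: np.ndarray | None = None
    pc_jitter: float = 0.2
    rank2_axis: np.ndarray | None = None
    rank2_jitter: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rr_sd_ms < 0:
            raise ValueError("rr_sd_ms must be non-negative")


@dataclass
class NoiseSpec:
    """Additive noise: white SD, 1/f^beta pink SD, 50 Hz line amplitude,
    and common reference-electrode noise.

    Line-noise harmonics are added at −20 dB per harmonic relative to the
    fundamental, with a fixed phase.  ``ref_noise_sd_uv`` models the
    recording reference electrode's own noise, which enters every channel
    referenced against it identically (and is therefore cancelled by
    re-referencing) — the textbook reason a quiet ventral reference helps.
    """

    white_sd_uv: float = 5.0
    pink_sd_uv: float = 3.0
    pink_exponent: float = 1.0
    line_amp_uv: float = 2.0
    line_freq_hz: float = 50.0
    n_harmonics: int = 3
    ref_noise_sd_uv: float = 5.0


@dataclass
class StimArtifactSpec:
    """Brief high-amplitude stimulation transient on every channel."""

    amplitude_uv: float = 400.0
    window_ms: tuple[float, float] = (-0.5, 3.0)
    enabled: bool = True


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic stimulation block."""

    fs: float = 10000.0
    n_trials: int = 2000
    isi_ms: float = 763.0
    jitter_ms: float = 50.0
    source: SourceSpec | None = None
    cardiac: CardiacSpec = field(default_factory=CardiacSpec)
    stim_artifact: StimArtifactSpec = field(default_factory=StimArtifactSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    montage: MontageSpec | None = None
    epoch_ms: tuple[float, float] = (-200.0, 700.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValueError("fs must be at least 1000 Hz")
        if self.montage is None:
            self.montage = builtin_montage("cervical")
        if self.source is None:
            self.source = SourceSpec(
                dipole_pattern(self.montage, center=(0.0, 0.0), scale_cm=2.0)
            )
        if self.isi_ms <= 0:
            raise ValueError("isi_ms must be positive")
        # consecutive epochs may overlap (763 ms ISI vs a −200..700 ms epoch
        # does in the emulated protocol); flag it but do not forbid it
        if self.isi_ms <= self.epoch_ms[1] - self.epoch_ms[0]:
            warnings.warn("inter-stimulus interval shorter than the epoch "
                          "span; consecutive epochs overlap")
        if self.jitter_ms >= self.isi_ms / 2:
            raise ValueError("jitter_ms must be below isi_ms / 2")
        if len(self.source.pattern) != len(self.montage.electrodes):
            raise ValueError("source pattern length must match montage size")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic recording."""

    event_samples: np.ndarray
    r_peak_samples: np.ndarray
    clean_evoked: np.ndarray          # grid channels x epoch samples, µV
    pattern: np.ndarray               # unit-norm dipole weights
    trial_amplitudes: np.ndarray      # per-trial peak magnitudes, µV
    epoch_ms: tuple[float, float] = (-200.0, 700.0)
    fs: float = 10000.0


def dipole_pattern(
    montage: MontageSpec, center: tuple[float, float], scale_cm: float
) -> np.ndarray:
    """Unit-norm Gaussian falloff exp(−d²/2s²) around ``center`` on the grid."""
    if scale_cm <= 0:
        raise ValueError("scale_cm must be positive")
    pos = np.array([(x, y) for _, _, x, y in montage.electrodes])
    c = np.asarray(center, dtype=float)
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    if np.any(c < lo - 2.0) or np.any(c > hi + 2.0):
        warnings.warn("dipole center lies far outside the electrode grid")
    d2 = ((pos - c) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * scale_cm**2))
    return w / np.linalg.norm(w)


def _triphasic_template(t_ms: np.ndarray, latency_ms: float, width_ms: float
                        ) -> np.ndarray:
    """Triphasic wave: small early positive lobe, main negative peak, slow
    late positive lobe; difference of Gaussians normalized to −1 at its
    deepest point."""
    def g(mu, sd):
        return np.exp(-0.5 * ((t_ms - mu) / sd) ** 2)

    w = -g(latency_ms, width_ms)
    w += 0.35 * g(latency_ms - 1.8 * width_ms, 0.7 * width_ms)
    w += 0.45 * g(latency_ms + 2.5 * width_ms, 2.0 * width_ms)
    return w / abs(w.min())


def default_cardiac_template(
    n_channels: int, fs: float, amp_uv: float = 100.0, duration_ms: float = 250.0,
    seed: int = 12345,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel cardiac artifact waveform and its rank-1 variation axis.

    The waveform is a QRS-like sharp biphasic deflection plus a slow T-like
    lobe, with smoothly varying amplitude/polarity across channels (the
    artifact projects with different gain over the grid).  The variation
    axis is the temporal derivative, so beat-to-beat jitter mimics small
    latency/shape changes.
    """
    n = int(round(duration_ms * fs / 1000.0)) | 1
    t = (np.arange(n) - n // 2) / fs * 1000.0  # ms, centred on the R-peak
    qrs = np.exp(-0.5 * (t / 8.0) ** 2) - 0.45 * np.exp(-0.5 * ((t - 16) / 9.0) ** 2)
    twave = 0.25 * np.exp(-0.5 * ((t - 90) / 30.0) ** 2)
    wave = qrs + twave
    rng = np.random.default_rng(seed)
    gains = 1.0 + 0.5 * np.sin(np.linspace(0, np.pi, n_channels))
    gains *= np.where(rng.random(n_channels) < 0.15, -1.0, 1.0)
    template = amp_uv * gains[:, None] * wave[None, :]
    axis = np.gradient(template, axis=1)
    axis *= np.linalg.norm(template) / max(np.linalg.norm(axis), 1e-30)
    return template, axis


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                beta: float) -> np.ndarray:
    """Unit-SD 1/f^beta noise via spectral shaping of white noise."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    scale[0] = 0.0
    spec = np.fft.rfft(white, axis=1) * scale[None, :]
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _event_train(rng: np.random.Generator, cfg: SimulationConfig,
                 start_ms: float) -> np.ndarray:
    # uniform jitter in integer-ms steps, as in the stimulation protocol
    steps = int(round(cfg.jitter_ms))
    jit = rng.integers(-steps, steps + 1, size=cfg.n_trials).astype(float)
    onsets_ms = start_ms + np.arange(cfg.n_trials) * cfg.isi_ms + jit
    return np.round(onsets_ms * cfg.fs / 1000.0).astype(int)


def _r_peak_train(rng: np.random.Generator, cfg: SimulationConfig,
                  n_samples: int) -> np.ndarray:
    rr_min_ms = 300.0
    peaks = []
    t_ms = 400.0 + 200.0 * rng.random()
    while t_ms * cfg.fs / 1000.0 < n_samples - 1:
        peaks.append(int(round(t_ms * cfg.fs / 1000.0)))
        rr = rng.normal(cfg.cardiac.rr_mean_ms, cfg.cardiac.rr_sd_ms)
        t_ms += max(rr, rr_min_ms)
    return np.array(peaks, dtype=int)


def _add_windowed(data: np.ndarray, wave: np.ndarray, center: int,
                  half: int) -> None:
    """Add channels × (2*half+1) ``wave`` centred at sample ``center``,
    truncating at recording bounds."""
    lo = max(center - half, 0)
    hi = min(center + half + 1, data.shape[1])
    data[:, lo:hi] += wave[:, lo - (center - half): wave.shape[1] - (center + half + 1 - hi)]


def _generate(cfg: SimulationConfig, task: bool) -> tuple[Recording, SimTruth]:
    rng = np.random.default_rng(cfg.seed)
    montage = cfg.montage
    n_grid = len(montage.electrodes)
    grid_chs = montage.channel_infos(role="esg")
    ventral_label = "AC" if montage.name == "cervical" else "AL"
    channels = grid_chs + [
        ChannelInfo(ventral_label, role="esg", patch="none"),
        ChannelInfo("ECG", role="ecg", patch="none"),
    ]
    n_ch = len(channels)

    # --- timing (identical draws for task and rest: paired surrogates) ---
    pre_ms = -cfg.epoch_ms[0] + 100.0
    events = _event_train(rng, cfg, start_ms=pre_ms + cfg.jitter_ms + 10.0)
    n_samples = int(events[-1] + (cfg.epoch_ms[1] + 100.0) * cfg.fs / 1000.0)

    src = cfg.source
    amps = src.amplitude_uv * (
        1.0 + src.amplitude_cv * rng.standard_normal(cfg.n_trials)
    )
    amps = np.clip(amps, 0.0, None)

    r_peaks = _r_peak_train(rng, cfg, n_samples)
    card = cfg.cardiac
    beat_z = rng.standard_normal(len(r_peaks))
    beat_z2 = rng.standard_normal(len(r_peaks))

    data = np.zeros((n_ch, n_samples))

    # --- noise (same realization for task and rest) ---
    noi = cfg.noise
    if noi.white_sd_uv > 0:
        data += noi.white_sd_uv * rng.standard_normal((n_ch, n_samples))
    if noi.pink_sd_uv > 0:
        data += noi.pink_sd_uv * _pink_noise(
            rng, (n_ch, n_samples), cfg.fs, noi.pink_exponent
        )
    if noi.ref_noise_sd_uv > 0:
        # reference-electrode noise: identical on every channel recorded
        # against the spinal reference (the ECG has its own reference)
        ref = noi.ref_noise_sd_uv * rng.standard_normal(n_samples)
        data[: n_grid + 1] += ref[None, :]
    if noi.line_amp_uv > 0:
        t = np.arange(n_samples) / cfg.fs
        for h in range(1, noi.n_harmonics + 1):
            f = noi.line_freq_hz * h
            if f >= cfg.fs / 2:
                break
            amp = noi.line_amp_uv * 10.0 ** (-(h - 1))  # −20 dB per harmonic
            data += amp * np.sin(2 * np.pi * f * t + 0.7 * h)[None, :]

    # --- cardiac artifacts on grid + ventral channels, ECG trace ---
    if card.enabled:
        template = card.template
        if template is None:
            template, axis = default_cardiac_template(n_grid + 1, cfg.fs)
        else:
            axis = card.variation_axis
            if axis is None:
                axis = np.zeros_like(template)
        half = template.shape[1] // 2
        ecg_wave = _ecg_waveform(template.shape[1], cfg.fs)
        for k, p in enumerate(r_peaks):
            beat = template + card.pc_jitter * beat_z[k] * axis
            if card.rank2_axis is not None and card.rank2_jitter > 0:
                beat = beat + card.rank2_jitter * beat_z2[k] * card.rank2_axis
            _add_windowed(data[: n_grid + 1], beat, p, half)
            _add_windowed(data[n_grid + 1:], ecg_wave[None, :], p, half)

    # --- evoked source + stimulation transient (task only) ---
    ep0, ep1 = cfg.epoch_ms
    n_ep = int(round((ep1 - ep0) * cfg.fs / 1000.0)) + 1
    t_ep = ep0 + np.arange(n_ep) * 1000.0 / cfg.fs
    template_t = _triphasic_template(t_ep, src.latency_ms, src.width_ms)
    # amplitude_uv is the peak at the best electrode: rescale the unit-norm
    # pattern so its largest weight is 1
    profile = src.pattern / src.pattern.max()
    spatial = np.concatenate([profile, [-src.ventral_gain]])
    clean_evoked = src.amplitude_uv * profile[:, None] * template_t[None, :]
    if task:
        i0 = int(round(-ep0 * cfg.fs / 1000.0))  # epoch sample of stimulus
        for k, ev in enumerate(events):
            lo = ev - i0
            data[: n_grid + 1, lo: lo + n_ep] += (
                amps[k] * spatial[:, None] * template_t[None, :]
            )
        sa = cfg.stim_artifact
        if sa.enabled and sa.amplitude_uv > 0:
            w0 = int(round(sa.window_ms[0] * cfg.fs / 1000.0))
            w1 = int(round(sa.window_ms[1] * cfg.fs / 1000.0))
            pulse = sa.amplitude_uv * np.hanning(max(w1 - w0 + 1, 3))
            for ev in events:
                data[:, ev + w0: ev + w0 + len(pulse)] += pulse[None, :]

    rec = Recording(
        data, cfg.fs, channels, reference=montage.reference_label,
        events=[(int(s), STIM_CODE) for s in events],
    )
    truth = SimTruth(
        event_samples=events.copy(),
        r_peak_samples=r_peaks,
        clean_evoked=clean_evoked,
        pattern=src.pattern.copy(),
        trial_amplitudes=amps if task else np.zeros_like(amps),
        epoch_ms=cfg.epoch_ms,
        fs=cfg.fs,
    )
    return rec, truth


def _ecg_waveform(n: int, fs: float, amp_uv: float = 800.0) -> np.ndarray:
    t = (np.arange(n) - n // 2) / fs * 1000.0
    wave = np.exp(-0.5 * (t / 6.0) ** 2)           # R spike
    wave -= 0.18 * np.exp(-0.5 * ((t + 25) / 10.0) ** 2)   # Q
    wave -= 0.22 * np.exp(-0.5 * ((t - 30) / 12.0) ** 2)   # S
    wave += 0.3 * np.exp(-0.5 * ((t - 120) / 35.0) ** 2)   # T
    return amp_uv * wave


def generate_recording(cfg: SimulationConfig) -> tuple[Recording, SimTruth]:
    """Synthetic stimulation block with planted evoked source and artifacts.

    Deterministic given ``cfg.seed``; returns the recording together with
    its ground truth (event samples, R-peak samples, noiseless evoked
    template, dipole pattern, per-trial amplitudes).
    """
    return _generate(cfg, task=True)


def generate_resting_state(cfg: SimulationConfig) -> tuple[Recording, SimTruth]:
    """Resting-state surrogate: identical noise/cardiac realization, no
    evoked source or stimulation transients, same (surrogate) event train."""
    return _generate(cfg, task=False)


# ---------------------------------------------------------------------------
# ground-truth sidecar (plain-text TSV + JSON)


def write_truth(truth: SimTruth, base: str) -> None:
    """Write the SimTruth sidecar as ``base``.events.tsv / .rpeaks.tsv /
    .evoked.tsv / .json."""
    os.makedirs(os.path.dirname(base) or ".", exist_ok=True)
    np.savetxt(base + ".events.tsv", truth.event_samples[:, None], fmt="%d",
               header="sample", comments="")
    np.savetxt(base + ".rpeaks.tsv", truth.r_peak_samples[:, None], fmt="%d",
               header="sample", comments="")
    np.savetxt(base + ".evoked.tsv", truth.clean_evoked.T, fmt="%.9g",
               delimiter="\t")
    meta = {
        "pattern": truth.pattern.tolist(),
        "trial_amplitudes": truth.trial_amplitudes.tolist(),
        "epoch_ms": list(truth.epoch_ms),
        "fs": truth.fs,
    }
    with open(base + ".json", "w", encoding="utf-8") as f:
        json.dump(meta, f)


def load_truth(base: str) -> SimTruth:
    events = np.loadtxt(base + ".events.tsv", skiprows=1, dtype=int, ndmin=1)
    rpeaks = np.loadtxt(base + ".rpeaks.tsv", skiprows=1, dtype=int, ndmin=1)
    evoked = np.loadtxt(base + ".evoked.tsv", delimiter="\t", ndmin=2).T
    with open(base + ".json", encoding="utf-8") as f:
        meta = json.load(f)
    return SimTruth(
        event_samples=events,
        r_peak_samples=rpeaks,
        clean_evoked=evoked,
        pattern=np.array(meta["pattern"]),
        trial_amplitudes=np.array(meta["trial_amplitudes"]),
        epoch_ms=tuple(meta["epoch_ms"]),
        fs=meta["fs"],
    )
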