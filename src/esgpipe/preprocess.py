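"""Continuous-signal preprocessing: stimulation-artifact handling,
resampling, zero-phase filtering, re-referencing, threshold-based
rejection, and epoching with baseline correction.

Conventions: sample indexing is 0-based; epoch windows are inclusive at
both millisecond endpoints (−200..700 ms at 1 kHz is 901 samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .io_montage import ChannelInfo, Recording

__all__ = [
    "ArtifactWindow",
    "EpochSet",
    "RejectionRule",
    "detect_stim_artifact_window",
    "interpolate_artifact",
    "resample",
    "filter_zero_phase",
    "rereference",
    "reject_timepoints",
    "epoch_and_baseline",
    "interpolate_channels",
]

DEFAULT_WINDOW_MS = (-1.0, 4.0)


@dataclass
class ArtifactWindow:
    """Per-patch stimulation-artifact window relative to stimulus onset."""

    start_ms: float
    end_ms: float
    scope: str = "cervical"
    fallback: bool = False  # True when detection failed and the default was used

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("start_ms must precede end_ms")
        if self.end_ms - self.start_ms >= 50.0:
            raise ValueError("artifact window must be shorter than 50 ms")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trials × channels × time, baseline-corrected.

    ``retained`` marks trials free of rejected samples; averages and
    downstream training use retained trials only.
    """

    data: np.ndarray
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    fs: float
    retained: np.ndarray
    events: np.ndarray
    channels: list[ChannelInfo] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        t0, _ = self.window_ms
        return t0 + np.arange(self.data.shape[2]) * 1000.0 / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def average(self) -> np.ndarray:
        """Trial average over retained trials (channels × time)."""
        if not self.retained.any():
            raise ValueError("no retained trials")
        return self.data[self.retained].mean(axis=0)

    def time_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.window_ms[0]) * self.fs / 1000.0))


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def detect_stim_artifact_window(
    rec: Recording,
    events: np.ndarray,
    patch_labels: list[str],
    search_ms: tuple[float, float] = (-10.0, 10.0),
    k: float = 8.0,
    reenter_sd: float = 1.0,
    relative_exit: float = 0.02,
    pad_ms: float = 0.5,
) -> ArtifactWindow:
    """Locate the stimulation-artifact window in the trial-averaged signal.

    The grand mean over all events and all channels of one spinal patch is
    screened inside ``search_ms``.  The window is seeded at the maximum
    absolute deviation from the baseline mean (baseline: first quarter of
    the search window) provided it exceeds ``k`` baseline SDs, and expanded
    outwards until the deviation re-enters ``max(reenter_sd · SD,
    relative_exit · peak deviation)``.  The relative term keeps the window
    anchored to the transient itself: averaging shrinks the baseline SD far
    below the evoked response, so a pure SD criterion would otherwise chase
    the response.  ``pad_ms`` widens the detected bounds on both sides as a
    guard band against tapered artifact edges below the exit threshold.
    With no suprathreshold peak the default (−1, +4) ms window is returned
    with ``fallback=True``.
    """
    events = np.asarray(events, dtype=int)
    if len(events) < 10:
        raise ValueError("need at least 10 events to detect the artifact window")
    if not search_ms[0] < 0 < search_ms[1]:
        raise ValueError("search window must contain stimulus onset")
    idx = [rec.ch_index(lab) for lab in patch_labels]
    s0 = _ms_to_samples(search_ms[0], rec.fs)
    s1 = _ms_to_samples(search_ms[1], rec.fs)
    keep = (events + s0 >= 0) & (events + s1 < rec.n_samples)
    ev = events[keep]
    # grand mean over trials and patch channels
    offsets = np.arange(s0, s1 + 1)
    segs = rec.data[idx][:, ev[:, None] + offsets[None, :]]  # ch x trial x time
    g = segs.mean(axis=(0, 1))
    n_ref = max(len(g) // 4, 3)
    ref = g[:n_ref]
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        sd = 1e-12
    dev = np.abs(g - mu)
    peak = int(np.argmax(dev))
    scope = rec.channels[idx[0]].patch if idx else "cervical"
    if dev[peak] <= k * sd:
        return ArtifactWindow(*DEFAULT_WINDOW_MS, scope=scope, fallback=True)
    exit_thr = max(reenter_sd * sd, relative_exit * dev[peak])
    lo = hi = peak
    while lo > 0 and dev[lo - 1] > exit_thr:
        lo -= 1
    while hi < len(g) - 1 and dev[hi + 1] > exit_thr:
        hi += 1
    return ArtifactWindow(
        (s0 + lo) * 1000.0 / rec.fs - pad_ms,
        (s0 + hi) * 1000.0 / rec.fs + pad_ms,
        scope=scope,
    )


def interpolate_artifact(
    rec: Recording,
    events: np.ndarray,
    window: ArtifactWindow,
    n_context: int = 5,
) -> Recording:
    """Replace samples inside each event's artifact window by
    shape-preserving piecewise-cubic (PCHIP) interpolation.

    ``n_context`` anchor samples on each side of the window feed the
    interpolant; samples outside the windows are untouched.
    """
    out = rec.copy()
    events = np.sort(np.asarray(events, dtype=int))
    w0 = _ms_to_samples(window.start_ms, rec.fs)
    w1 = _ms_to_samples(window.end_ms, rec.fs)
    if len(events) > 1 and np.any(np.diff(events) <= (w1 - w0 + 2 * n_context)):
        raise ValueError("artifact windows overlap across consecutive events")
    for ev in events:
        lo, hi = ev + w0, ev + w1  # inclusive gap bounds
        a = max(lo - n_context, 0)
        b = min(hi + n_context, rec.n_samples - 1)
        anchors = np.concatenate([np.arange(a, lo), np.arange(hi + 1, b + 1)])
        if anchors.size < 4:
            raise ValueError("not enough context samples to interpolate")
        gap = np.arange(lo, hi + 1)
        for c in range(rec.n_channels):
            f = PchipInterpolator(anchors, rec.data[c, anchors])
            out.data[c, gap] = f(gap)
    return out


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with anti-alias filtering; events are remapped
    by index scaling."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    scale = target_fs / rec.fs
    events = [
        (int(round(s * scale)), code)
        for s, code in rec.events
        if int(round(s * scale)) < data.shape[1]
    ]
    return Recording(data, target_fs, [replace(c) for c in rec.channels],
                     rec.reference, events)


def filter_zero_phase(
    rec: Recording,
    band: tuple[float, float] | None = (30.0, 400.0),
    notch: tuple[float, float] | None = (48.0, 53.0),
    comb: tuple[float, int] | None = None,
    comb_bandwidth: float = 0.003,
    order: int = 4,
) -> Recording:
    """Forward–backward Butterworth filtering (zero phase, effective order
    doubled).

    ``band`` applies a band-pass, ``notch`` a band-stop, and ``comb``
    (base frequency, number of harmonics) a cascade of second-order notch
    sections at multiples of the base frequency with −3 dB bandwidth
    ``comb_bandwidth × fs/2`` — the classical parameterization of a
    line-noise comb.
    """
    out = rec.copy()
    nyq = rec.fs / 2.0
    try:
        if notch is not None:
            sos = signal.butter(order, notch, btype="bandstop", fs=rec.fs,
                                output="sos")
            out.data = signal.sosfiltfilt(sos, out.data, axis=1)
        if comb is not None:
            base, n_harm = comb
            bw = comb_bandwidth * nyq
            for h in range(1, n_harm + 1):
                f0 = base * h
                if f0 >= nyq:
                    break
                b, a = signal.iirnotch(f0, f0 / bw, fs=rec.fs)
                out.data = signal.filtfilt(b, a, out.data, axis=1)
        if band is not None:
            lo, hi = band
            if not 0 < lo < hi < nyq:
                raise ValueError("band edges must satisfy 0 < lo < hi < fs/2")
            sos = signal.butter(order, band, btype="bandpass", fs=rec.fs,
                                output="sos")
            out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"unstable filter design: {exc}") from exc
    if not np.isfinite(out.data).all():
        raise RuntimeError("filter produced non-finite output; check band edges "
                           "relative to the sampling rate")
    return out


def rereference(
    rec: Recording, mode: str, keep_original: bool = True
) -> Recording:
    """Re-reference to a named channel or to the channel average.

    When re-referencing to a channel, the previous reference is retained as
    an explicit (now non-flat) channel if ``keep_original`` and it is not
    already present, so the operation is invertible.
    """
    out = rec.copy()
    if mode == "average":
        out.data = out.data - out.data.mean(axis=0, keepdims=True)
        out.reference = "average"
        return out
    ref_sig = out.data[out.ch_index(mode)].copy()
    if mode == out.reference:
        warnings.warn(f"re-referencing to the current reference {mode!r}; "
                      "channel becomes flat")
    if keep_original and rec.reference and rec.reference not in out.labels:
        out.data = np.vstack([out.data, np.zeros((1, out.n_samples))])
        out.channels = out.channels + [ChannelInfo(rec.reference, role="other")]
    out.data = out.data - ref_sig[None, :]
    out.reference = mode
    return out


@dataclass
class RejectionRule:
    """One threshold rule: applies to channels of the given roles, on an
    optional band-filtered copy, flagging |x| above ``threshold_uv`` or
    above ``sd_mult`` per-channel SDs."""

    roles: tuple[str, ...] = ("esg",)
    threshold_uv: float | None = 100.0
    band: tuple[float, float] | None = None
    sd_mult: float | None = None


def reject_timepoints(
    rec: Recording,
    rules: list[RejectionRule] | None = None,
    drop_fraction: float = 0.5,
) -> tuple[np.ndarray, list[str]]:
    """Threshold-based sample rejection with whole-channel fallback.

    Returns ``(keep_mask, dropped)``: a boolean keep-mask over samples
    (union of all rules across surviving channels) and the labels of
    channels with more than ``drop_fraction`` flagged samples, which are
    dropped instead of contributing to the mask.
    """
    if rules is None:
        rules = [RejectionRule()]
    n = rec.n_samples
    flagged = np.zeros((rec.n_channels, n), dtype=bool)
    for rule in rules:
        idx = [i for i, c in enumerate(rec.channels) if c.role in rule.roles]
        if not idx:
            continue
        x = rec.data[idx]
        if rule.band is not None:
            sos = signal.butter(4, rule.band, btype="bandpass", fs=rec.fs,
                                output="sos")
            x = signal.sosfiltfilt(sos, x, axis=1)
        if rule.threshold_uv is not None:
            flagged[idx] |= np.abs(x) > rule.threshold_uv
        if rule.sd_mult is not None:
            sd = x.std(axis=1, keepdims=True)
            flagged[idx] |= np.abs(x) > rule.sd_mult * sd
    frac = flagged.mean(axis=1)
    drop = frac > drop_fraction
    dropped = [rec.channels[i].label for i in np.flatnonzero(drop)]
    keep_mask = ~flagged[~drop].any(axis=0) if (~drop).any() else np.zeros(n, bool)
    if not keep_mask.any() or (~drop).sum() == 0:
        raise RuntimeError("rejection removed all channels or samples")
    return keep_mask, dropped


def epoch_and_baseline(
    rec: Recording,
    events: np.ndarray,
    window_ms: tuple[float, float] = (-200.0, 700.0),
    baseline_ms: tuple[float, float] = (-110.0, -10.0),
    mask: np.ndarray | None = None,
    channel_labels: list[str] | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the per-trial baseline mean.

    Endpoints are inclusive: −200..700 ms at 1 kHz yields 901 samples.
    Trials overlapping rejected samples (``mask`` False) are kept in the
    array but marked not retained.
    """
    if not (window_ms[0] <= baseline_ms[0] < baseline_ms[1] <= window_ms[1]):
        raise ValueError("baseline window must lie inside the epoch window")
    events = np.asarray(events, dtype=int)
    w0 = _ms_to_samples(window_ms[0], rec.fs)
    w1 = _ms_to_samples(window_ms[1], rec.fs)
    if np.any(events + w0 < 0) or np.any(events + w1 >= rec.n_samples):
        raise ValueError("epoch window exceeds recording bounds for some events")
    if channel_labels is None:
        sub = rec
    else:
        sub = rec.pick(channel_labels)
    offsets = np.arange(w0, w1 + 1)
    data = sub.data[:, events[:, None] + offsets[None, :]]  # ch x tr x time
    data = np.transpose(data, (1, 0, 2)).copy()
    b0 = _ms_to_samples(baseline_ms[0] - window_ms[0], rec.fs)
    b1 = _ms_to_samples(baseline_ms[1] - window_ms[0], rec.fs)
    data -= data[:, :, b0: b1 + 1].mean(axis=2, keepdims=True)
    if mask is None:
        retained = np.ones(len(events), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        retained = np.array(
            [mask[ev + w0: ev + w1 + 1].all() for ev in events]
        )
    if not retained.any():
        raise RuntimeError("no retained trials after masking")
    return EpochSet(data, window_ms, baseline_ms, rec.fs, retained, events,
                    channels=[replace(c) for c in sub.channels])


def interpolate_channels(rec: Recording, bad_labels: list[str],
                         power: float = 2.0) -> Recording:
    """Convenience inverse-distance-weighted reconstruction of dropped grid
    channels from their positioned neighbours (not a spherical spline)."""
    out = rec.copy()
    good = [i for i, c in enumerate(rec.channels)
            if c.label not in bad_labels and c.position is not None]
    for lab in bad_labels:
        i = rec.ch_index(lab)
        pos = rec.channels[i].position
        if pos is None or not good:
            raise ValueError(f"cannot interpolate unpositioned channel {lab!r}")
        d = np.array([np.hypot(pos[0] - rec.channels[j].position[0],
                               pos[1] - rec.channels[j].position[1])
                      for j in good])
        w = 1.0 / np.maximum(d, 1e-6) ** power
        w /= w.sum()
        out.data[i] = w @ rec.data[good]
    return out
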