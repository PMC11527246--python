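"""Evoked-response measures: peak latency/amplitude, SNR, time-frequency.

Amplitude and latency are read at the extremum of expected polarity in
the trial-averaged trace; when no peak clears the visibility criterion
(|peak| ≥ k · baseline SD, default k = 2) the amplitude is read at a
group-level fallback latency and the measure flagged not visible.  SNR is
the RMS in a ±1 ms window around the peak divided by the RMS of a
same-length pre-stimulus window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["EvokedMeasure", "peak_measure", "snr", "time_frequency"]


@dataclass
class EvokedMeasure:
    """Peak measure for one participant/condition/source."""

    latency_ms: float
    amplitude: float
    snr: float = np.nan
    visible: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.snr) and self.snr < 0:
            raise ValueError("snr must be non-negative")


def peak_measure(
    avg_trace: np.ndarray,
    times_ms: np.ndarray,
    search_ms: tuple[float, float],
    polarity: int,
    detection_k: float = 2.0,
    group_latency_ms: float | None = None,
    baseline_ms: tuple[float, float] = (-110.0, -10.0),
    source: str = "",
) -> EvokedMeasure:
    """Latency and amplitude of the evoked peak in an average trace.

    The extremum of the stated polarity inside ``search_ms`` is the
    candidate peak; it is accepted when its magnitude reaches
    ``detection_k`` baseline standard deviations, otherwise the measure is
    flagged not visible and the amplitude is read at ``group_latency_ms``
    (the across-participant average latency).
    """
    avg_trace = np.asarray(avg_trace, dtype=float).ravel()
    times_ms = np.asarray(times_ms, dtype=float).ravel()
    if polarity not in (-1, 1):
        raise ValueError("polarity must be -1 or +1")
    win = (times_ms >= search_ms[0]) & (times_ms <= search_ms[1])
    if not win.any():
        raise ValueError("search window outside the trace")
    seg = polarity * avg_trace[win]
    j = int(np.argmax(seg))
    latency = float(times_ms[win][j])
    amplitude = float(avg_trace[win][j])
    base = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
    sd = float(avg_trace[base].std()) if base.any() else 0.0
    if abs(amplitude) >= detection_k * sd:
        return EvokedMeasure(latency, amplitude, visible=True, source=source)
    if group_latency_ms is None:
        raise ValueError(
            "peak below the visibility criterion and no group fallback "
            "latency supplied"
        )
    i = int(np.argmin(np.abs(times_ms - group_latency_ms)))
    return EvokedMeasure(float(times_ms[i]), float(avg_trace[i]),
                         visible=False, source=source)


def snr(
    avg_trace: np.ndarray,
    times_ms: np.ndarray,
    latency_ms: float,
    halfwidth_ms: float = 1.0,
    noise_mode: str = "mirror",
    noise_end_ms: float = -10.0,
) -> float:
    """RMS(signal window) / RMS(noise window).

    The signal window is ``latency_ms ± halfwidth_ms``.  The noise window
    has the same sample length and lies before stimulus onset: mirrored at
    ``−latency_ms`` (``noise_mode="mirror"``, default) or ending at
    ``noise_end_ms`` (``noise_mode="pre_stim_end"``).
    """
    avg_trace = np.asarray(avg_trace, dtype=float).ravel()
    times_ms = np.asarray(times_ms, dtype=float).ravel()
    fs = 1000.0 / np.median(np.diff(times_ms))
    half_n = int(round(halfwidth_ms * fs / 1000.0))
    i_pk = int(np.argmin(np.abs(times_ms - latency_ms)))
    sig = avg_trace[i_pk - half_n: i_pk + half_n + 1]
    if noise_mode == "mirror":
        i_n = int(np.argmin(np.abs(times_ms + latency_ms)))
    elif noise_mode == "pre_stim_end":
        i_n = int(np.argmin(np.abs(times_ms - (noise_end_ms - halfwidth_ms))))
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    noi = avg_trace[i_n - half_n: i_n + half_n + 1]
    if len(sig) != 2 * half_n + 1 or len(noi) != 2 * half_n + 1:
        raise ValueError("signal or noise window exceeds the trace")
    rms_n = float(np.sqrt(np.mean(noi**2)))
    rms_s = float(np.sqrt(np.mean(sig**2)))
    if rms_n == 0:
        warnings.warn("zero noise RMS; returning infinite SNR")
        return np.inf
    return rms_s / rms_n


def time_frequency(
    avg_trace: np.ndarray,
    fs: float,
    times_ms: np.ndarray,
    win_ms: float = 21.0,
    baseline_ms: tuple[float, float] = (-200.0, -10.0),
    nfft: int = 1024,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous short-time FFT magnitude, baseline-ratio normalized.

    A Hann window of ``win_ms`` slides sample-by-sample (hop 1); the
    magnitude map is zero-padded to ``nfft`` points and every frequency
    row is divided by its mean over ``baseline_ms``.  Returns
    ``(freqs_hz, out_times_ms, tf_map)`` with ``tf_map`` of shape
    frequencies × time.
    """
    avg_trace = np.asarray(avg_trace, dtype=float).ravel()
    n_win = int(round(win_ms * fs / 1000.0))
    if n_win < 3:
        raise ValueError("window too short for the sampling rate")
    span_ms = baseline_ms[1] - baseline_ms[0]
    if win_ms > span_ms:
        raise ValueError("STFT window longer than the baseline interval")
    stft = signal.ShortTimeFFT(
        signal.windows.hann(n_win, sym=False), hop=1, fs=fs, mfft=nfft,
        scale_to="magnitude",
    )
    S = np.abs(stft.stft(avg_trace))
    # centre-of-window time axis in the trace's millisecond frame
    t_out = times_ms[0] + stft.t(len(avg_trace)) * 1000.0
    keep = (t_out >= times_ms[0]) & (t_out <= times_ms[-1])
    S, t_out = S[:, keep], t_out[keep]
    base = (t_out >= baseline_ms[0]) & (t_out <= baseline_ms[1])
    if not base.any():
        raise ValueError("baseline interval outside the trace")
    denom = S[:, base].mean(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    return stft.f, t_out, S / denom
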