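"""Cardiac-artifact removal: R-peak detection and a per-channel optimal
basis set (OBS).

Surface spinal recordings carry severe cardiac artifacts.  The removal
follows the PCA-based optimal-basis-set approach developed for
ballistocardiogram cleanup: per channel, all heartbeat-locked segments
(−0.5·median(RR) .. +0.5·median(RR) around each R-peak) form an
artifact × time matrix; the basis is the mean artifact plus the first
four principal components of the centred matrix; each beat's segment is
then least-squares fitted by the basis and the fit subtracted.  Samples
outside all cardiac windows are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["RPeakSeries", "OBSModel", "detect_r_peaks", "fit_obs",
           "remove_cardiac", "remove_cardiac_multichannel"]


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices plus the median RR."""

    peak_samples: np.ndarray
    median_rr: float  # samples

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=int)
        if np.any(np.diff(self.peak_samples) <= 0):
            raise ValueError("peak samples must be strictly increasing")
        if self.median_rr <= 0:
            raise ValueError("median RR must be positive")


@dataclass
class OBSModel:
    """Five-vector basis per channel: [mean artifact, PC1..PC4]."""

    basis: np.ndarray             # 5 x window_length
    window: tuple[int, int]       # (−half, +half) samples around the peak

    def __post_init__(self) -> None:
        if self.basis.shape[0] != 5:
            raise ValueError("basis must hold exactly 5 vectors")
        if not np.isfinite(self.basis).all():
            raise ValueError("basis contains non-finite values")
        if self.window[0] != -self.window[1]:
            raise ValueError("window must be symmetric about the peak")

    def to_hdf5(self, path: str) -> None:
        """Dump the basis for inspection."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("basis", data=self.basis)
            f.attrs["window"] = self.window

    @classmethod
    def from_hdf5(cls, path: str) -> "OBSModel":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(basis=f["basis"][()], window=tuple(f.attrs["window"]))


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_ms: float = 300.0,
    override: np.ndarray | None = None,
) -> RPeakSeries:
    """Detect one R-peak per cardiac cycle in a single-channel ECG.

    A band-passed (8–40 Hz where possible), squared and smoothed energy
    envelope is screened with :func:`scipy.signal.find_peaks` under a
    refractory distance, and each detection is refined to the largest
    absolute raw deflection within ±50 ms.  Externally curated annotations
    bypass detection entirely via ``override``.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if override is not None:
        peaks = np.sort(np.asarray(override, dtype=int))
        rr = np.diff(peaks)
        return RPeakSeries(peaks, float(np.median(rr)) if rr.size else fs)
    if len(ecg) < 5 * fs:
        raise ValueError("need at least 5 s of ECG signal")
    if not np.isfinite(ecg).all() or np.ptp(ecg) == 0:
        raise RuntimeError("flat or undefined ECG signal; cannot detect R-peaks")
    hi = min(40.0, fs / 2 * 0.9)
    sos = signal.butter(2, (8.0, hi), btype="bandpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, ecg - ecg.mean()) ** 2
    smooth_n = max(int(round(0.1 * fs)), 1)
    env = np.convolve(env, np.ones(smooth_n) / smooth_n, mode="same")
    height = 0.3 * np.percentile(env, 99)
    locs, _ = signal.find_peaks(env, height=height,
                                distance=int(round(refractory_ms * fs / 1000.0)))
    if locs.size < 2:
        raise RuntimeError("fewer than two cardiac cycles detected")
    half = int(round(0.05 * fs))
    refined = []
    for p in locs:
        lo, hi_ = max(p - half, 0), min(p + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(np.abs(ecg[lo:hi_] - np.median(ecg)))))
    peaks = np.unique(refined)
    rr = np.diff(peaks)
    return RPeakSeries(peaks, float(np.median(rr)))


def _beat_segments(channel: np.ndarray, peaks: RPeakSeries
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    half = int(np.floor(0.5 * peaks.median_rr))
    ok = (peaks.peak_samples - half >= 0) & (
        peaks.peak_samples + half < len(channel)
    )
    interior = peaks.peak_samples[ok]
    offsets = np.arange(-half, half + 1)
    segs = channel[interior[:, None] + offsets[None, :]]
    return segs, interior, half


def fit_obs(channel: np.ndarray, peaks: RPeakSeries, n_pcs: int = 4,
            variance_threshold: float | None = None) -> OBSModel:
    """Fit the optimal basis set on one channel.

    The artifact matrix stacks every complete heartbeat window
    (2·⌊0.5·median(RR)⌋+1 samples).  PCA runs on the matrix after removing
    the mean artifact, so "mean + PCs" forms a non-redundant basis.  With
    ``variance_threshold`` set, the PC count is instead the smallest
    number explaining that fraction of centred variance (capped at 4).
    """
    channel = np.asarray(channel, dtype=float).ravel()
    segs, interior, half = _beat_segments(channel, peaks)
    if segs.shape[0] < 6:
        raise RuntimeError(
            f"only {segs.shape[0]} complete artifact windows; need at least 6"
        )
    if segs.shape[0] < 10:
        warnings.warn("fewer than 10 complete artifact windows; OBS may be "
                      "poorly conditioned")
    mean_art = segs.mean(axis=0)
    centred = segs - mean_art
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if variance_threshold is not None:
        var = s**2 / max((s**2).sum(), 1e-30)
        n_pcs = min(int(np.searchsorted(np.cumsum(var), variance_threshold) + 1), 4)
    pcs = np.zeros((4, segs.shape[1]))
    k = min(n_pcs, vt.shape[0])
    pcs[:k] = vt[:k]
    basis = np.vstack([mean_art, pcs])
    return OBSModel(basis=basis, window=(-half, half))


def remove_cardiac(channel: np.ndarray, model: OBSModel,
                   peaks: RPeakSeries) -> np.ndarray:
    """Subtract the per-beat least-squares OBS fit from one channel.

    Each beat's window is clipped at the midpoints between adjacent
    R-peaks (so short RR intervals never double-correct a sample) and at
    the recording bounds; edge beats are fitted on their truncated window.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    out = channel.copy()
    p = peaks.peak_samples
    half = model.window[1]
    for i, peak in enumerate(p):
        lo = peak - half
        hi = peak + half
        if i > 0:
            lo = max(lo, (p[i - 1] + peak + 1) // 2)
        if i < len(p) - 1:
            hi = min(hi, (peak + p[i + 1]) // 2 - 1)
        lo = max(lo, 0)
        hi = min(hi, len(channel) - 1)
        if hi - lo + 1 < 5:
            continue
        cols = slice(lo - peak + half, hi - peak + half + 1)
        design = model.basis[:, cols].T  # window x 5
        seg = channel[lo: hi + 1]
        coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
        out[lo: hi + 1] = seg - design @ coef
    return out


def remove_cardiac_multichannel(
    data: np.ndarray, peaks: RPeakSeries, n_pcs: int = 4
) -> np.ndarray:
    """Fit and remove the OBS on every row of a channels × samples array."""
    out = np.empty_like(data)
    for c in range(data.shape[0]):
        model = fit_obs(data[c], peaks, n_pcs=n_pcs)
        out[c] = remove_cardiac(data[c], model, peaks)
    return out
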