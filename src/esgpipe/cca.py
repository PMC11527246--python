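"""Canonical correlation average regression (CCAR) spatial filtering.

CCAR trains participant-specific spatial filters by running canonical
correlation analysis between X — all single-trial windows concatenated in
time (channels × N·n_win) — and Y — the trial average tiled N times with
the same layout.  The procedure acts as a template match between single
trials and their average: the leading filter separates the evoked
response from background noise.  Filters are trained on a short window
around the expected response peak (±5 ms, i.e. 11 samples at 1 kHz) and
then applied to the whole epoch.  Activation patterns are obtained by
multiplying the filters with the data covariance, making the weights
interpretable as sensor-space topographies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import EpochSet

__all__ = [
    "TrainMatrices",
    "SpatialFilterModel",
    "StabilityResult",
    "build_train_matrices",
    "train_ccar",
    "select_component",
    "apply_filter",
    "stability_control",
    "stability_compare",
]


@dataclass
class TrainMatrices:
    """X (concatenated single-trial windows) and Y (tiled trial average)."""

    X: np.ndarray
    Y: np.ndarray
    n_trials: int
    n_win_samples: int
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have identical shapes")
        if self.X.shape[1] != self.n_trials * self.n_win_samples:
            raise ValueError("column count must equal n_trials * n_win_samples")


@dataclass
class SpatialFilterModel:
    """Trained CCAR filters, correlations, patterns and selection state."""

    Wx: np.ndarray                  # channels x components
    Wy: np.ndarray
    corrs: np.ndarray               # canonical correlations, descending
    patterns: np.ndarray            # channels x components (Cov(X) @ Wx)
    train_window_ms: tuple[float, float]
    selected: int | None = None
    sign: int = 1
    channel_labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.Wx.shape[1]

    def selected_filter(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("no component selected yet")
        return self.sign * self.Wx[:, self.selected]

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("Wx", "Wy", "corrs", "patterns"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["train_window_ms"] = self.train_window_ms
            f.attrs["selected"] = -1 if self.selected is None else self.selected
            f.attrs["sign"] = self.sign
            if self.channel_labels is not None:
                f.attrs["channel_labels"] = self.channel_labels

    @classmethod
    def from_hdf5(cls, path: str) -> "SpatialFilterModel":
        import h5py

        with h5py.File(path, "r") as f:
            sel = int(f.attrs["selected"])
            labels = f.attrs.get("channel_labels")
            return cls(
                Wx=f["Wx"][()], Wy=f["Wy"][()], corrs=f["corrs"][()],
                patterns=f["patterns"][()],
                train_window_ms=tuple(f.attrs["train_window_ms"]),
                selected=None if sel < 0 else sel,
                sign=int(f.attrs["sign"]),
                channel_labels=None if labels is None else list(labels),
            )


def build_train_matrices(
    epochs: EpochSet, window_ms: tuple[float, float],
    min_samples_per_feature: int = 50,
) -> TrainMatrices:
    """Assemble X/Y from retained trials inside ``window_ms``.

    The window is inclusive at both endpoints: ±5 ms at 1 kHz gives 11
    samples per trial.  A warning is raised when the column count falls
    below ``min_samples_per_feature`` × channels, the sample-to-feature
    ratio recommended for reliable canonical correlations.
    """
    t0, t1 = window_ms
    if t0 < epochs.window_ms[0] or t1 > epochs.window_ms[1]:
        raise ValueError("training window must lie inside the epoch window")
    data = epochs.retained_data()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 retained trials")
    i0 = epochs.time_index(t0)
    n_win = int(round((t1 - t0) * epochs.fs / 1000.0)) + 1
    wins = data[:, :, i0: i0 + n_win]                   # tr x ch x win
    n_trials, n_ch, _ = wins.shape
    X = np.transpose(wins, (1, 0, 2)).reshape(n_ch, n_trials * n_win)
    avg = wins.mean(axis=0)                              # ch x win
    Y = np.tile(avg, (1, n_trials))
    if X.shape[1] < min_samples_per_feature * n_ch:
        warnings.warn(
            f"only {X.shape[1]} training samples for {n_ch} channels; "
            f"fewer than {min_samples_per_feature} samples per feature"
        )
    return TrainMatrices(X, Y, n_trials, n_win, window_ms)


def _inv_sqrt(C: np.ndarray, reg: float) -> tuple[np.ndarray, int]:
    """Regularized inverse square root via eigendecomposition; returns the
    numerical rank retained."""
    dim = C.shape[0]
    Cr = C + reg * (np.trace(C) / dim) * np.eye(dim)
    w, V = np.linalg.eigh(Cr)
    tol = w.max() * dim * np.finfo(float).eps
    keep = w > tol
    rank = int(keep.sum())
    if rank == 0:
        raise np.linalg.LinAlgError(
            "covariance is numerically zero; increase regularization or check "
            "the input scaling"
        )
    inv = V[:, keep] / np.sqrt(w[keep])[None, :]
    return inv, rank


def train_ccar(tm: TrainMatrices, regularization: float = 1e-6
               ) -> SpatialFilterModel:
    """Solve the CCA problem between X and Y.

    Covariances are whitened (with ridge ε·trace/dim added, ε =
    ``regularization``) and the canonical directions obtained from the
    singular decomposition of the whitened cross-covariance.  Components
    are ordered by canonical correlation; with rank-deficient data the
    retained component count equals the numerical rank.
    """
    X, Y = tm.X, tm.Y
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    try:
        Wxx, rank_x = _inv_sqrt(Cxx, regularization)
        Wyy, rank_y = _inv_sqrt(Cyy, regularization)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{exc} (X full rank required when regularization = 0)"
        ) from exc
    K = Wxx.T @ Cxy @ Wyy
    U, s, Vt = np.linalg.svd(K)
    k = min(rank_x, rank_y)
    Wx = Wxx @ U[:, :k]
    Wy = Wyy @ Vt.T[:, :k]
    corrs = np.clip(s[:k], 0.0, 1.0)
    patterns = Cxx @ Wx
    return SpatialFilterModel(Wx=Wx, Wy=Wy, corrs=corrs, patterns=patterns,
                              train_window_ms=tm.window_ms)


def select_component(
    model: SpatialFilterModel,
    epochs: EpochSet,
    expected_latency_ms: float,
    expected_polarity: int,
    latency_tol_ms: float = 3.0,
    target_channel: str | None = None,
    n_candidates: int = 2,
) -> SpatialFilterModel:
    """Select and sign-normalize one CCA component.

    Among the first ``n_candidates`` components (the selected component is
    empirically always among the first two), a component qualifies when
    the filtered trial-average peaks within ``±latency_tol_ms`` of
    ``expected_latency_ms`` and — if ``target_channel`` is given — its
    activation pattern couples positively into the target electrode after
    sign normalization (the expected dipole orientation: the target sensor
    deflects with the component's polarity).  The sign is set so the average
    peak has ``expected_polarity`` (−1 for a negativity); ties break
    toward the lower (higher-correlation) index.
    """
    if expected_polarity not in (-1, 1):
        raise ValueError("expected_polarity must be -1 or +1")
    avg = epochs.average()
    times = epochs.times_ms
    lo = expected_latency_ms - 3 * latency_tol_ms
    hi = expected_latency_ms + 3 * latency_tol_ms
    search = (times >= lo) & (times <= hi)
    if not search.any():
        raise ValueError("search window outside the epoch")
    target_idx = (
        epochs.labels.index(target_channel) if target_channel else None
    )
    diagnostics = []
    for k in range(min(n_candidates, model.n_components)):
        trace = model.Wx[:, k] @ avg
        seg = trace[search]
        j = int(np.argmax(np.abs(seg)))
        peak_t = times[search][j]
        peak_v = seg[j]
        sign = 1 if np.sign(peak_v) == expected_polarity else -1
        lat_ok = abs(peak_t - expected_latency_ms) <= latency_tol_ms
        if target_idx is not None:
            # after sign normalization the component trace carries the
            # expected polarity, so a dipole peaking over the target must
            # couple positively into the target electrode
            pat_ok = sign * model.patterns[target_idx, k] > 0
        else:
            pat_ok = True
        diagnostics.append(
            f"component {k}: peak {peak_v:+.3g} at {peak_t:.1f} ms "
            f"(latency {'ok' if lat_ok else 'off'}, pattern "
            f"{'ok' if pat_ok else 'mismatch'})"
        )
        if lat_ok and pat_ok:
            return replace(model, selected=k, sign=sign)
    raise RuntimeError(
        "no CCA component qualifies for selection:\n  " + "\n  ".join(diagnostics)
    )


def apply_filter(model: SpatialFilterModel, epochs: EpochSet,
                 component: int | None = None) -> np.ndarray:
    """Project every epoch through the (sign-normalized) selected filter.

    Returns trials × time single-trial component traces in arbitrary
    units; linear in the data, so the training average maps onto the
    selected canonical variate up to scale.
    """
    k = model.selected if component is None else component
    if k is None:
        raise ValueError("select a component first (or pass `component`)")
    if epochs.data.shape[1] != model.Wx.shape[0]:
        raise ValueError("channel count differs between model and epochs")
    if model.channel_labels is not None and epochs.channels:
        if epochs.labels != model.channel_labels:
            raise ValueError("channel order differs between model and epochs")
    w = model.sign * model.Wx[:, k]
    return np.einsum("c,tcs->ts", w, epochs.data)


@dataclass
class StabilityResult:
    """Subsample-stability control: pairwise |correlation| of first-component
    time-courses across repeated 50 % subsample trainings."""

    mean_abs_corr: float
    abs_corrs: np.ndarray          # off-diagonal pairwise values
    traces: np.ndarray             # n_rep x n_win component time-courses


def _first_component_trace(epochs: EpochSet, idx: np.ndarray,
                           window_ms: tuple[float, float]) -> np.ndarray:
    sub = EpochSet(
        epochs.data[idx], epochs.window_ms, epochs.baseline_ms, epochs.fs,
        np.ones(len(idx), dtype=bool), epochs.events[idx], epochs.channels,
    )
    tm = with_warnings_suppressed(build_train_matrices, sub, window_ms)
    model = train_ccar(tm)
    avg = sub.average()
    i0 = sub.time_index(window_ms[0])
    return model.Wx[:, 0] @ avg[:, i0: i0 + tm.n_win_samples]


def with_warnings_suppressed(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


def stability_control(
    epochs: EpochSet,
    window_ms: tuple[float, float],
    frac: float = 0.5,
    n_rep: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Train CCAR on random ``frac`` subsamples of the retained trials,
    ``n_rep`` times, and measure the mean pairwise absolute correlation of
    the first-component time-courses inside the training window.

    Strong planted evoked activity yields correlations near 1; on
    structureless (resting) data the subsampled components decorrelate.
    Run on a task epoch set and on a rest surrogate with identical trial
    timings, the two distributions feed a one-tailed paired comparison
    across participants (see :func:`esgpipe.stats.paired_t`).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    retained_idx = np.flatnonzero(epochs.retained)
    n_sub = max(int(round(frac * len(retained_idx))), 2)
    traces = []
    for _ in range(n_rep):
        if frac >= 1.0:
            idx = retained_idx
        else:
            idx = rng.choice(retained_idx, size=n_sub, replace=False)
        traces.append(_first_component_trace(epochs, idx, window_ms))
    T = np.asarray(traces)
    Z = T - T.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    C = (Z / norms) @ (Z / norms).T
    iu = np.triu_indices(n_rep, k=1)
    abs_corrs = np.abs(C[iu])
    return StabilityResult(float(abs_corrs.mean()), abs_corrs, T)


def stability_compare(task_means, rest_means):
    """One-tailed paired comparison (task > rest) of per-participant mean
    subsample correlations from :func:`stability_control`."""
    from .stats import paired_t

    return paired_t(task_means, rest_means, tail="greater")
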