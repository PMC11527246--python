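"""Monte-Carlo robustness curves: how many trials (per participant) and
how many participants (group level) yield significant evoked responses.

Both analyses resample single-trial peak amplitudes with replacement.
The participant-level curve resamples trials per participant and tests
the sampled amplitudes against zero; the group-level curve first
resamples participants, then trials within each resampled participant,
averages the trials, and tests the participant means.  Spatial filters
are assumed trained once on all trials beforehand — the resamples reuse
the resulting amplitudes rather than re-training per repetition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RobustnessCurve", "participant_trial_curve", "group_experiment_sim"]

DEFAULT_TRIAL_GRID = tuple(range(5, 1000, 10)) + (1000,)


class RobustnessCurve:
    """Proportion of significant repetitions over a resampling grid."""

    def __init__(self, proportions: np.ndarray, trial_counts: np.ndarray,
                 participant_counts: np.ndarray | None, n_rep: int,
                 alpha: float, seed: int, row_label: str):
        self.proportions = proportions
        self.trial_counts = np.asarray(trial_counts, dtype=int)
        self.participant_counts = (
            None if participant_counts is None
            else np.asarray(participant_counts, dtype=int)
        )
        self.n_rep = n_rep
        self.alpha = alpha
        self.seed = seed
        self.row_label = row_label
        if np.any(np.diff(self.trial_counts) <= 0):
            raise ValueError("trial grid must be strictly increasing")
        if not ((proportions >= 0) & (proportions <= 1)).all():
            raise ValueError("proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (row, n_trials, proportion) for plotting."""
        rows = (
            self.participant_counts
            if self.participant_counts is not None
            else np.arange(self.proportions.shape[0])
        )
        recs = [
            {self.row_label: int(r), "n_trials": int(k),
             "proportion": float(self.proportions[i, j])}
            for i, r in enumerate(rows)
            for j, k in enumerate(self.trial_counts)
        ]
        return pd.DataFrame.from_records(recs)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _t_pvals_two(x: np.ndarray) -> np.ndarray:
    """Two-sided one-sample t p values along the last axis, vectorized."""
    k = x.shape[-1]
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1, ddof=1)
    sd = np.maximum(sd, np.finfo(float).tiny)
    t = mean / (sd / np.sqrt(k))
    return 2.0 * sps.t.sf(np.abs(t), k - 1)


def participant_trial_curve(
    amplitudes: list[np.ndarray],
    trial_counts=DEFAULT_TRIAL_GRID,
    n_rep: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tail: str = "two",
) -> RobustnessCurve:
    """Per-participant proportion of significant one-sample t tests when
    resampling ``k`` trials with replacement, for every k in the grid.

    ``amplitudes`` holds one vector of single-trial peak amplitudes per
    participant.  ``tail="two"`` by default; a one-sided option
    ("greater"/"less") is available for signed hypotheses.
    """
    if not amplitudes:
        raise ValueError("no amplitude vectors supplied")
    amplitudes = [np.asarray(a, dtype=float).ravel() for a in amplitudes]
    if any(len(a) < 2 for a in amplitudes):
        raise ValueError("each participant needs at least 2 trials")
    trial_counts = np.asarray(trial_counts, dtype=int)
    rng = np.random.default_rng(seed)
    props = np.empty((len(amplitudes), len(trial_counts)))
    for i, amp in enumerate(amplitudes):
        for j, k in enumerate(trial_counts):
            idx = rng.integers(0, len(amp), size=(n_rep, k))
            p = _tail_pvals(amp[idx], tail)
            props[i, j] = float(np.mean(p < alpha))
    return RobustnessCurve(props, trial_counts, None, n_rep, alpha, seed,
                           row_label="participant")


def _tail_pvals(x: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two":
        return _t_pvals_two(x)
    k = x.shape[-1]
    mean = x.mean(axis=-1)
    sd = np.maximum(x.std(axis=-1, ddof=1), np.finfo(float).tiny)
    t = mean / (sd / np.sqrt(k))
    if tail == "greater":
        return sps.t.sf(t, k - 1)
    if tail == "less":
        return sps.t.cdf(t, k - 1)
    raise ValueError(f"unknown tail {tail!r}")


def group_experiment_sim(
    amplitudes: list[np.ndarray],
    participant_counts=(5, 10, 15, 20, 25, 30, 35, 36),
    trial_counts=DEFAULT_TRIAL_GRID,
    n_rep: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tail: str = "two",
) -> RobustnessCurve:
    """Simulated group experiments: resample participants, then trials,
    average trials per participant, and t-test the participant means.

    Each resampled participant occurrence draws its trials independently.
    Returns the proportion of significant repetitions per
    (participant count, trial count) cell.
    """
    if len(amplitudes) < 2:
        raise ValueError("need at least 2 participants")
    amplitudes = [np.asarray(a, dtype=float).ravel() for a in amplitudes]
    participant_counts = np.asarray(participant_counts, dtype=int)
    trial_counts = np.asarray(trial_counts, dtype=int)
    if np.any(participant_counts < 2):
        raise ValueError("participant counts must be at least 2 "
                         "(no group variance otherwise)")
    if np.any(np.diff(participant_counts) <= 0):
        raise ValueError("participant grid must be strictly increasing")
    lens = np.array([len(a) for a in amplitudes])
    padded = np.zeros((len(amplitudes), lens.max()))
    for i, a in enumerate(amplitudes):
        padded[i, : len(a)] = a
    rng = np.random.default_rng(seed)
    props = np.empty((len(participant_counts), len(trial_counts)))
    for i, n_p in enumerate(participant_counts):
        for j, k in enumerate(trial_counts):
            pidx = rng.integers(0, len(amplitudes), size=(n_rep, n_p))
            # uniform within each resampled participant's own trial count
            u = rng.random(size=(n_rep, n_p, k))
            tidx = np.floor(u * lens[pidx][:, :, None]).astype(int)
            means = padded[pidx[:, :, None], tidx].mean(axis=-1)
            p = _tail_pvals(means, tail)
            props[i, j] = float(np.mean(p < alpha))
    return RobustnessCurve(props, trial_counts, participant_counts, n_rep,
                           alpha, seed, row_label="n_participants")
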