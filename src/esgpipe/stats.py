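"""Inferential layer: t-tests with effect sizes, the interaction-ratio
integration statistic, spatiotemporal cluster-based permutation testing,
and noncentral-t power / sample-size computation.

The cluster test compares two paired conditions sample-by-sample with
paired t-tests, clusters suprathreshold samples of equal sign under
channel-and-time adjacency, and evaluates each cluster's mass (summed t)
against the maximum-mass distribution obtained by randomly sign-flipping
the per-participant condition differences.  With n participants such that
2^n ≤ 4096 the sign-flip null is enumerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TestResult",
    "AttenuationMeasure",
    "Cluster",
    "ClusterResult",
    "one_sample_t",
    "paired_t",
    "interaction_ratio",
    "cluster_permutation",
    "power_one_sample",
    "sample_size_power",
]

_TAILS = ("two", "greater", "less")


@dataclass
class TestResult:
    """t statistic, p value, two-sided 95 % CI of the mean, Cohen's d."""

    statistic: float
    p_value: float
    ci_95: tuple[float, float]
    cohens_d: float
    n: int
    tail: str = "two"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")
        if self.ci_95[0] > self.ci_95[1]:
            raise ValueError("confidence bounds out of order")


def _alternative(tail: str) -> str:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    return {"two": "two-sided", "greater": "greater", "less": "less"}[tail]


def one_sample_t(values: np.ndarray, tail: str = "two") -> TestResult:
    """One-sample t test against zero with 95 % CI and Cohen's d = mean/SD."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t statistic undefined")
    res = sps.ttest_1samp(x, 0.0, alternative=_alternative(tail))
    ci = sps.ttest_1samp(x, 0.0).confidence_interval(0.95)
    return TestResult(float(res.statistic), float(res.pvalue),
                      (float(ci.low), float(ci.high)),
                      float(x.mean() / sd), len(x), tail)


def paired_t(a: np.ndarray, b: np.ndarray, tail: str = "two") -> TestResult:
    """Paired t test, implemented as a one-sample test on the differences.

    Identical inputs (all differences zero) are reported as a degenerate
    null result (t = 0, p = 1) rather than an error.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return TestResult(0.0, 1.0, (0.0, 0.0), 0.0, len(d), tail,
                              degenerate=True)
        raise ValueError("constant nonzero differences; t undefined")
    return one_sample_t(d, tail)


def interaction_ratio(d1, d2, d12):
    """Interaction ratio in percent: 100 · ((D1 + D2) − D1D2) / (D1 + D2).

    Quantifies attenuation of the response to simultaneous two-digit
    stimulation relative to the sum of the single-digit responses: 0 %
    means additivity (no integration), positive values attenuation,
    negative values amplification.  Accepts scalars or arrays
    (elementwise, e.g. one value per participant).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d12 = np.asarray(d12, dtype=float)
    denom = d1 + d2
    if np.any(denom == 0):
        raise ZeroDivisionError("undefined interaction ratio: D1 + D2 = 0")
    out = 100.0 * (denom - d12) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class AttenuationMeasure:
    """Single-digit amplitudes, double-digit amplitude and their IR."""

    d1: float
    d2: float
    d12: float
    ir_percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.ir_percent = interaction_ratio(self.d1, self.d2, self.d12)


# ---------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class Cluster:
    channels: tuple[int, ...]
    time_range: tuple[int, int]     # inclusive sample-index bounds
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    alpha: float
    adjacency: str
    t_observed: np.ndarray
    max_mass_null: np.ndarray

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _edges(adjacency: np.ndarray, n_ch: int, n_t: int
           ) -> tuple[np.ndarray, np.ndarray]:
    """Flattened spatiotemporal edge list: consecutive time samples within a
    channel plus adjacent channels at equal time."""
    nodes = np.arange(n_ch * n_t).reshape(n_ch, n_t)
    eu = [nodes[:, :-1].ravel()]
    ev = [nodes[:, 1:].ravel()]
    ia, ja = np.nonzero(np.triu(adjacency, k=1))
    for a, b in zip(ia, ja):
        eu.append(nodes[a])
        ev.append(nodes[b])
    return np.concatenate(eu), np.concatenate(ev)


def _max_masses_python(tmat: np.ndarray, thr: float, eu: np.ndarray,
                       ev: np.ndarray, n_nodes: int) -> np.ndarray:
    out = np.empty(tmat.shape[0])
    for p in range(tmat.shape[0]):
        t = tmat[p]
        s = np.where(t > thr, 1, np.where(t < -thr, -1, 0))
        active = (s[eu] != 0) & (s[eu] == s[ev])
        graph = coo_matrix(
            (np.ones(active.sum()), (eu[active], ev[active])),
            shape=(n_nodes, n_nodes),
        )
        _, labels = connected_components(graph, directed=False)
        hot = s != 0
        if not hot.any():
            out[p] = 0.0
            continue
        masses = np.bincount(labels[hot], weights=t[hot])
        out[p] = np.abs(masses).max() if masses.size else 0.0
    return out


def _build_numba_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is normally present
        return None

    @njit(cache=True)
    def kernel(tmat, thr, eu, ev, n_nodes):
        n_perm = tmat.shape[0]
        out = np.empty(n_perm)
        parent = np.empty(n_nodes, np.int64)
        for p in range(n_perm):
            t = tmat[p]
            for i in range(n_nodes):
                parent[i] = i
            for e in range(eu.shape[0]):
                a, b = eu[e], ev[e]
                ta, tb = t[a], t[b]
                if (ta > thr and tb > thr) or (ta < -thr and tb < -thr):
                    ra = a
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = b
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        parent[ra] = rb
            mass = np.zeros(n_nodes)
            for i in range(n_nodes):
                ti = t[i]
                if ti > thr or ti < -thr:
                    r = i
                    while parent[r] != r:
                        r = parent[r]
                    mass[r] += ti
            best = 0.0
            for i in range(n_nodes):
                m = abs(mass[i])
                if m > best:
                    best = m
            out[p] = best
        return out

    return kernel


_NUMBA_KERNEL = None
_NUMBA_TRIED = False


def _max_masses(tmat, thr, eu, ev, n_nodes):
    global _NUMBA_KERNEL, _NUMBA_TRIED
    if not _NUMBA_TRIED:
        _NUMBA_KERNEL = _build_numba_kernel()
        _NUMBA_TRIED = True
    if _NUMBA_KERNEL is not None:
        return _NUMBA_KERNEL(tmat, thr, eu, ev, n_nodes)
    return _max_masses_python(tmat, thr, eu, ev, n_nodes)


def _t_from_signs(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t statistics for every sign-flip pattern at once.

    ``diffs`` is participants × features; ``signs`` permutations ×
    participants of ±1.  The per-feature sum of squares is invariant under
    sign flips, so only the flipped means need recomputing.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n
    ss = (diffs**2).sum(axis=0)
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def _sign_patterns(n: int, n_perm: int, exact_limit: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    if 2**n <= exact_limit:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return 2.0 * bits - 1.0, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # include the identity so p is never zero
    return signs, False


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    time_window: tuple[int, int] | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    exact_limit: int = 4096,
) -> ClusterResult:
    """Spatiotemporal cluster-based permutation test between paired
    conditions (participants × channels × time).

    Suprathreshold samples (|t| above the two-sided critical value at
    ``cluster_alpha``) of equal sign and connected under channel adjacency
    or consecutive time form clusters scored by their summed t (mass).
    Cluster p values are the fraction of sign-flip permutations whose
    maximum cluster mass reaches the observed mass; with 2^n participants'
    sign patterns below ``exact_limit`` the null is enumerated exactly.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape or cond_a.ndim != 3:
        raise ValueError("conditions must be matched participants x channels "
                         "x time arrays")
    n_sub, n_ch, n_t_full = cond_a.shape
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must be channels x channels")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p values are coarse")
    n_islands, _ = connected_components(coo_matrix(adjacency), directed=False)
    if n_islands > 1:
        warnings.warn(f"channel adjacency splits into {n_islands} islands; "
                      "clusters cannot bridge them")
    sl = slice(None) if time_window is None else slice(time_window[0],
                                                       time_window[1] + 1)
    diffs = (cond_a - cond_b)[:, :, sl]
    n_t = diffs.shape[2]
    t_off = 0 if time_window is None else time_window[0]
    diffs2d = diffs.reshape(n_sub, n_ch * n_t)
    thr = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, n_sub - 1))
    eu, ev = _edges(adjacency, n_ch, n_t)
    n_nodes = n_ch * n_t

    # observed statistics and clusters
    t_obs = _t_from_signs(diffs2d, np.ones((1, n_sub)))[0]
    s = np.where(t_obs > thr, 1, np.where(t_obs < -thr, -1, 0))
    active = (s[eu] != 0) & (s[eu] == s[ev])
    graph = coo_matrix((np.ones(active.sum()), (eu[active], ev[active])),
                       shape=(n_nodes, n_nodes))
    _, labels = connected_components(graph, directed=False)
    clusters: list[Cluster] = []
    hot = np.flatnonzero(s != 0)
    for lab in np.unique(labels[hot]):
        members = np.flatnonzero((labels == lab) & (s != 0))
        mass = float(t_obs[members].sum())
        chs = tuple(sorted(set(members // n_t)))
        ts = members % n_t
        clusters.append(Cluster(chs, (int(ts.min() + t_off),
                                      int(ts.max() + t_off)),
                                mass, 1.0, int(np.sign(mass))))

    rng = np.random.default_rng(seed)
    signs, exact = _sign_patterns(n_sub, n_perm, exact_limit, rng)
    t_perm = _t_from_signs(diffs2d, signs)
    null = _max_masses(np.ascontiguousarray(t_perm), thr, eu, ev, n_nodes)
    for c in clusters:
        c.p_value = float(np.mean(null >= abs(c.mass)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters, len(signs), cluster_alpha, alpha,
        adjacency=("exact-enumeration " if exact else "") +
        f"{int(adjacency.sum() // 2)} channel pairs",
        t_observed=t_obs.reshape(n_ch, n_t),
        max_mass_null=null,
    )


# ---------------------------------------------------------------------------
# noncentral-t power and sample size


def power_one_sample(n: int, d: float, alpha: float = 0.05,
                     tail: str = "greater") -> float:
    """Power of a one-sample t test at effect size d (noncentral t,
    ncp = |d|·√n)."""
    if n < 2:
        return 0.0
    ncp = abs(d) * np.sqrt(n)
    df = n - 1
    if tail == "two":
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - sps.nct.cdf(tcrit, df, ncp)
                     + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.ppf(1.0 - alpha, df)
    return float(1.0 - sps.nct.cdf(tcrit, df, ncp))


def sample_size_power(d: float, alpha: float = 0.05, power: float = 0.90,
                      tail: str = "greater", n_max: int = 1_000_000) -> int:
    """Smallest n whose one-sample t test reaches the target power.

    The one-tailed defaults match the preregistration convention used for
    evoked-potential amplitude tests (directional hypotheses).
    """
    if d == 0:
        raise ValueError("effect size must be nonzero")
    if not 0 < alpha < power < 1:
        raise ValueError("require 0 < alpha < power < 1")
    n = 2
    while n <= n_max:
        if power_one_sample(n, d, alpha, tail) >= power:
            return n
        n += 1
    raise RuntimeError(f"target power unreachable below n = {n_max}")
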