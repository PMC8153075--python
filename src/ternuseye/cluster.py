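"""Nonparametric cluster-based permutation tests for paired time series.

Paired condition differences are reduced to a pointwise paired t series;
contiguous supra-threshold runs (cluster-forming threshold = two-tailed t
critical value at alpha, df = n-1) become clusters whose mass is the sum
of t inside the run.  The null distribution is the maximum absolute
cluster mass over random per-participant sign flips of the differences
(exact exchangeability under the paired null), and each observed cluster's
p-value is (1 + #{null >= |mass|}) / (n_iterations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    mass: float
    p_value: float = np.nan


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_iterations: int
    alpha: float
    threshold: float
    seed: int | None = None
    null_max_mass: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    window_ms: tuple = (500.0, 1000.0)


def pointwise_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t statistic at each time point for condition matrices
    (participants x time); zero-variance points get t = 0 with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have the same shape")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return _t_from_diff(a - b)


def _t_from_diff(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance time points: t set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t


def form_clusters(t_series: np.ndarray, threshold: float,
                  grid_ms: np.ndarray | None = None) -> list[Cluster]:
    """Maximal contiguous runs with t > +threshold or t < -threshold.

    Cluster extent is half-open [first sample, last sample + dt).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t_series = np.asarray(t_series, dtype=float)
    if grid_ms is None:
        grid_ms = np.arange(len(t_series), dtype=float)
    grid_ms = np.asarray(grid_ms, dtype=float)
    dt = float(grid_ms[1] - grid_ms[0]) if len(grid_ms) > 1 else 1.0
    clusters = []
    for sign in (1, -1):
        above = (t_series * sign) > threshold
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], above.view(np.int8), [0]))))
        for s, e in zip(edges[0::2], edges[1::2]):
            clusters.append(Cluster(float(grid_ms[s]), float(grid_ms[e - 1]) + dt,
                                    sign, float(t_series[s:e].sum())))
    clusters.sort(key=lambda c: c.start_ms)
    return clusters


def _max_cluster_masses(tmat: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise maximum absolute cluster mass (0 when no cluster)."""
    tmat = np.atleast_2d(tmat)
    out = np.zeros(tmat.shape[0])
    for i, row in enumerate(tmat):
        best = 0.0
        for sign in (1.0, -1.0):
            above = (row * sign) > threshold
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(
                ([0], above.view(np.int8), [0]))))
            for s, e in zip(edges[0::2], edges[1::2]):
                best = max(best, abs(row[s:e].sum()))
        out[i] = best
    return out


def permutation_test(a: np.ndarray, b: np.ndarray, n_iterations: int = 1000,
                     alpha: float = 0.05, seed: int | None = None,
                     grid_ms: np.ndarray | None = None) -> ClusterTestResult:
    """Paired cluster-based permutation test of condition A vs B.

    ``a`` and ``b`` are participants x time matrices on a shared grid.
    Sign-flip permutations are vectorized: only the mean changes under a
    flip of d_i (the per-participant sum of squares is invariant), so the
    whole null t matrix is computed in one pass.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_iterations < 100:
        warnings.warn("fewer than 100 permutation iterations: p-values are "
                      "coarse", stacklevel=2)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    d = a - b
    threshold = float(sps.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    t_obs = _t_from_diff(d)
    clusters = form_clusters(t_obs, threshold, grid_ms)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_iterations, n))
    means = signs @ d / n                         # iterations x time
    ss = (d ** 2).sum(axis=0)                     # invariant under sign flips
    var = (ss - n * means ** 2) / (n - 1)
    np.clip(var, 0.0, None, out=var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var == 0, 0.0, means / np.sqrt(var / n))
    null_max = _max_cluster_masses(t_null, threshold)

    for c in clusters:
        c.p_value = (1.0 + np.sum(null_max >= abs(c.mass))) / (n_iterations + 1.0)
    return ClusterTestResult(clusters, n_iterations, alpha, threshold,
                             seed=seed, null_max_mass=null_max)


def delta_correlation(delta_ms_rate, delta_behavior,
                      window_ms: tuple = (500.0, 1000.0)) -> CorrelationResult:
    """Pearson correlation between per-participant sound-minus-baseline
    microsaccade-rate change and group-motion report change."""
    x = np.asarray(delta_ms_rate, dtype=float)
    y = np.asarray(delta_behavior, dtype=float)
    if x.shape != y.shape:
        raise ValueError("delta vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 participants")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the delta vectors")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), len(x), float(p), window_ms)
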