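"""Community detection on expression profiles under the distance d = 1 - r.

Two genes are close when their profiles are positively correlated (d -> 0)
and maximally distant when perfectly anti-correlated (d -> 2), so
anti-correlated genes land in different communities — the property the
switch-gene definition relies on.  Clustering is a k-means-style Lloyd
iteration on row-standardized profiles: because 1 - r is proportional to
the squared Euclidean distance between standardized profiles, assigning
each gene to the centroid with smallest d and recomputing centroids as
re-standardized mean profiles locally minimizes the total within-cluster
correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["ClusterAssignment", "correlation_distance", "cluster_expression", "choose_k"]


@dataclass
class ClusterAssignment:
    """Gene -> community label (1..n_communities) plus the achieved quality
    (total correlation distance of profiles to their cluster centroid)."""

    labels: pd.Series
    n_communities: int
    quality: float

    def __post_init__(self) -> None:
        present = set(self.labels.unique())
        expected = set(range(1, self.n_communities + 1))
        if present != expected:
            raise ValueError(f"labels {sorted(present)} != 1..{self.n_communities}")

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rows so that u_i . u_j = r(x_i, x_j)."""
    x = np.asarray(x, dtype=float)
    z = x - x.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-variance profile")
    return z / norm


def correlation_distance(x, y) -> float:
    """d = 1 - r(x, y): 0 for perfectly correlated profiles, 2 for perfectly
    anti-correlated, 1 for uncorrelated."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must share a length >= 3")
    ux, uy = _standardize(x), _standardize(y)
    return float(np.clip(1.0 - ux @ uy, 0.0, 2.0))


def _lloyd(u: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    n = u.shape[0]
    centroids = u[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        # distance to centroids: d = 1 - u.c ; ties -> lowest cluster index
        sim = u @ centroids.T
        new_labels = np.argmax(sim, axis=1)
        # refill emptied clusters from the worst-fitting point
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(sim[np.arange(n), new_labels]))
                new_labels[worst] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            m = u[labels == c].mean(axis=0)
            m = m - m.mean()
            norm = np.linalg.norm(m)
            if norm == 0:  # degenerate centroid: re-seed at random member
                m = u[labels == c][0]
                norm = 1.0
            centroids[c] = m / norm
    quality = float(np.sum(1.0 - (u @ centroids.T)[np.arange(n), labels]))
    return labels, quality


def cluster_expression(
    em, k: int, seed: int, restarts: int = 10, max_iter: int = 100
) -> ClusterAssignment:
    """Partition genes into ``k`` communities minimizing total d = 1 - r to
    the community centroid; deterministic given ``seed``, best of
    ``restarts`` random initializations."""
    vals = em.values if isinstance(em, ExpressionMatrix) else pd.DataFrame(em)
    n = vals.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    u = _standardize(vals.to_numpy())
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        labels, quality = _lloyd(u, k, rng, max_iter)
        if best is None or quality < best[1] - 1e-12:
            best = (labels, quality)
    labels, quality = best
    # compact 1..N labels in order of first appearance for determinism
    order = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    series = pd.Series([order[l] for l in labels], index=vals.index, name="community")
    return ClusterAssignment(series, n_communities=len(order), quality=quality)


def choose_k(
    em,
    k_range: tuple[int, int],
    seed: int,
    tol: float = 0.05,
    restarts: int = 10,
) -> int:
    """Elbow rule on the mean within-cluster distance.

    Qualities are compared per gene (mean d to centroid, a [0, 2] scale):
    the chosen k is the smallest whose improvement over k+1 drops below
    ``tol``.  The absolute scale makes structureless data (every further
    split only shaves noise) stop at the bottom of the range instead of
    chasing ever-smaller relative gains.  Falls back to the top of the
    range with a warning when the curve never flattens.
    """
    kmin, kmax = k_range
    vals = em.values if isinstance(em, ExpressionMatrix) else pd.DataFrame(em)
    n = vals.shape[0]
    if not 2 <= kmin <= kmax <= n:
        raise ValueError("k_range must lie within [2, n_genes]")
    seeds = np.random.SeedSequence(seed).generate_state(kmax - kmin + 1) % (2**31 - 1)
    mean_quality = {
        k: cluster_expression(em, k, int(s), restarts).quality / n
        for k, s in zip(range(kmin, kmax + 1), seeds)
    }
    for k in range(kmin, kmax):
        if mean_quality[k] - mean_quality[k + 1] < tol:
            return k
    warnings.warn(f"no elbow found in k range {k_range}; returning {kmax}")
    return kmax
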