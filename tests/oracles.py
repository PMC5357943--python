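"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct loops over edges and pairs,
exact integer arithmetic, explicit permutation resampling — and shares no
code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_link_counts(g, labels: dict):
    """Per-node (k, k_in, {module: count}) by enumerating incident edges."""
    out = {}
    for n in g.nodes:
        ks: dict = {}
        for m in g.neighbors(n):
            ks[labels[m]] = ks.get(labels[m], 0) + 1
        k = sum(ks.values())
        out[n] = (k, ks.get(labels[n], 0), ks)
    return out


def brute_cartography(g, labels: dict):
    """P, z, K_pi, z_g, APCC per non-isolated node, all by direct loops."""
    counts = brute_link_counts(g, labels)
    live = [n for n in g.nodes if counts[n][0] > 0]
    modules = sorted({labels[n] for n in live})
    internal = {c: [counts[n][1] for n in live if labels[n] == c] for c in modules}
    total = {c: [counts[n][0] for n in live if labels[n] == c] for c in modules}

    def pop_stats(xs):
        mu = sum(xs) / len(xs)
        var = sum((x - mu) ** 2 for x in xs) / len(xs)
        return mu, math.sqrt(var)

    out = {}
    for n in live:
        k, k_in, ks = counts[n]
        p = 1.0 - sum((v / k) ** 2 for v in ks.values())
        k_pi = 1.0 - (k_in / k) ** 2
        mu_i, sd_i = pop_stats(internal[labels[n]])
        z = 0.0 if sd_i == 0 else (k_in - mu_i) / sd_i
        mu_t, sd_t = pop_stats(total[labels[n]])
        z_g = 0.0 if sd_t == 0 else (k_in - mu_t) / sd_t
        rs = [g.edges[n, m]["r"] for m in g.neighbors(n)]
        out[n] = {"k": k, "k_in": k_in, "P": p, "z": z,
                  "K_pi": k_pi, "z_g": z_g, "APCC": sum(rs) / len(rs)}
    return out


def bfs_average_shortest_path(g) -> float:
    """Connected-pairs mean shortest path via hand-rolled BFS from every node."""
    total, pairs = 0, 0
    nodes = list(g.nodes)
    for src in nodes:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v, d in dist.items():
            if v != src:
                total += d
                pairs += 1
    if pairs == 0:
        return float("nan")
    return total / pairs  # ordered pairs: equals unordered mean


def pearson_sum_of_products(x, y) -> float:
    """Textbook r = [n Σxy − Σx Σy] / sqrt([n Σx² − (Σx)²][n Σy² − (Σy)²])."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx * sx) * (n * syy - sy * sy)
    )


def exact_hypergeom_tails(N: int, K: int, n: int) -> list[float]:
    """Exact upper tails P(X >= k), k = 0..min(n, K), for
    X ~ Hypergeom(N, K, n), by integer-arithmetic suffix summation."""
    kmax = min(n, K)
    numerators = [math.comb(K, k) * math.comb(N - K, n - k) for k in range(kmax + 1)]
    denom = math.comb(N, n)
    tails = []
    acc = 0
    for k in range(kmax, -1, -1):
        acc += numerators[k]
        tails.append(acc / denom)
    return tails[::-1]  # tails[k] = P(X >= k)


def logrank_chi2(times, events, group_a_mask) -> float:
    """Scalar unweighted log-rank chi-square computed from first principles."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    a = np.asarray(group_a_mask, dtype=bool)
    u = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & a).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & a).sum()
        u += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else u * u / var


def permutation_logrank_p(times, events, group_a_mask, n_perm: int, seed: int) -> float:
    """Permutation p-value of the log-rank statistic: shuffle group labels,
    recompute the chi-square (vectorized over permutations), and report the
    fraction at least as extreme as the observed value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    a = np.asarray(group_a_mask, dtype=bool)
    observed = logrank_chi2(times, events, a)

    uniq = np.unique(times[events])
    at_risk = times[None, :] >= uniq[:, None]              # (T, n)
    dying = (times[None, :] == uniq[:, None]) & events      # (T, n)
    n_at_risk = at_risk.sum(axis=1).astype(float)
    d_total = dying.sum(axis=1).astype(float)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(a) for _ in range(n_perm)])  # (P, n)
    n1 = at_risk @ perms.T.astype(float)                    # (T, P)
    d1 = dying @ perms.T.astype(float)
    frac = n1 / n_at_risk[:, None]
    u = (d1 - d_total[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_total[:, None] * frac * (1 - frac)
            * ((n_at_risk[:, None] - d_total[:, None])
               / np.maximum(n_at_risk[:, None] - 1, 1))
        ).sum(axis=0)
        chi2 = np.where(var > 0, u * u / var, 0.0)
    return float(np.mean(chi2 >= observed - 1e-12))
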