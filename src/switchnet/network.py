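"""Correlation-network construction from expression profiles.

Nodes are genes; an edge joins two genes whenever the absolute Pearson
correlation of their expression profiles meets the cutoff, and the edge
stores the *signed* correlation (anti-correlated edges are never rectified
— downstream neighbor statistics need the sign).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .io import ExpressionMatrix

__all__ = ["pearson_matrix", "build_graph", "threshold_scan", "degree_summary"]


def _values_of(em) -> pd.DataFrame:
    return em.values if isinstance(em, ExpressionMatrix) else pd.DataFrame(em)


def pearson_matrix(em) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene expression profiles.

    Requires >= 3 samples and non-zero variance for every gene (filter
    constant genes first; a zero-variance gene is a hard error naming it).
    """
    vals = _values_of(em)
    if vals.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate expression profiles")
    sd = vals.std(axis=1, ddof=0)
    flat = vals.index[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance genes (filter first): {list(flat)[:10]}")
    corr = np.corrcoef(vals.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=vals.index, columns=vals.index)


def build_graph(corr: pd.DataFrame, cutoff: float) -> nx.Graph:
    """Threshold a correlation matrix into an undirected graph.

    Edge (i, j) exists iff ``|r(i, j)| >= cutoff`` (inclusive); the signed r
    is stored as the edge attribute ``r``.  Nodes that end up with no edges
    stay in the node set flagged ``isolated=True``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    c = np.asarray(corr, dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    genes = list(corr.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(np.abs(c) >= cutoff, k=1))
    g.add_edges_from(
        (genes[i], genes[j], {"r": float(c[i, j])}) for i, j in zip(ii, jj)
    )
    for n in g.nodes:
        g.nodes[n]["isolated"] = g.degree(n) == 0
    return g


def threshold_scan(corr: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Audit the cutoff choice: per cutoff, nodes with edges, edge count and
    the fraction of non-isolated nodes in the largest connected component."""
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    rows = []
    for c in cutoffs:
        g = build_graph(corr, c)
        connected = [n for n in g if g.degree(n) > 0]
        if connected:
            sub = g.subgraph(connected)
            biggest = max(nx.connected_components(sub), key=len)
            frac = len(biggest) / len(connected)
        else:
            frac = 0.0
        rows.append(
            {
                "cutoff": c,
                "n_nodes_with_edges": len(connected),
                "n_edges": g.number_of_edges(),
                "fraction_in_largest_component": frac,
            }
        )
    return pd.DataFrame(rows)


def degree_summary(g: nx.Graph) -> tuple[pd.DataFrame, pd.Series]:
    """Degree histogram (degree, count) plus the per-node degree series."""
    deg = pd.Series(dict(g.degree()), name="degree").sort_index()
    hist = (
        deg.value_counts().sort_index().rename_axis("degree").reset_index(name="count")
    )
    return hist, deg
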