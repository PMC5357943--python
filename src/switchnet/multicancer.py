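"""Cross-dataset comparison of switch-gene (and neighbor) sets.

Each dataset's switch list is encoded as a binary column over the union of
observed genes; datasets are compared by Hamming distance and grouped by
average-linkage hierarchical clustering, mirroring how a panel of tumor
types can be organised by shared switch-gene signatures.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "build_membership_matrix",
    "hamming_distance_matrix",
    "cluster_datasets",
    "shared_genes",
    "compare_neighbor_sets",
    "linkage_to_newick",
]


def build_membership_matrix(lists: dict) -> pd.DataFrame:
    """Binary genes x datasets membership matrix over the union of all sets.

    Rows are sorted lexicographically; every row has at least one 1 by
    construction.  Fewer than two datasets is a hard error.
    """
    if len(lists) < 2:
        raise ValueError("need >= 2 datasets to compare")
    universe = sorted(set().union(*[set(v) for v in lists.values()]))
    if not universe:
        raise ValueError("all datasets are empty")
    mat = pd.DataFrame(0, index=pd.Index(universe, name="gene"), columns=list(lists))
    for name, genes in lists.items():
        mat.loc[sorted(set(genes)), name] = 1
    return mat


def hamming_distance_matrix(m: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Pairwise Hamming distance between dataset columns (count of rows where
    the binary memberships differ; divided by the row count if normalized)."""
    if m.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    x = m.to_numpy(dtype=int).T
    diff = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
    if normalize:
        diff /= m.shape[0]
    return pd.DataFrame(diff, index=m.columns, columns=m.columns)


def cluster_datasets(dist: pd.DataFrame, method: str = "average"):
    """Agglomerative clustering of the dataset distance matrix.

    Returns ``(Z, leaf_order, newick)``: the scipy linkage matrix, the
    dataset names in dendrogram leaf order, and a Newick rendering.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("invalid distance matrix")
    z = linkage(squareform(d, checks=False), method=method)
    order = [dist.columns[i] for i in leaves_list(z)]
    return z, order, linkage_to_newick(z, list(dist.columns))


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths =
    height differences between merges)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(i: int) -> str:
        if i < n:
            return str(labels[i])
        a, b, h, _ = z[i - n]
        heights[i] = h
        parts = []
        for child in (int(a), int(b)):
            child_h = heights.get(child, 0.0) if child >= n else 0.0
            parts.append(f"{render(child)}:{h - child_h:g}")
        return "(" + ",".join(parts) + ")"

    # render bottom-up so child heights are known
    for i in range(n, n + len(z)):
        heights[i] = z[i - n][2]
    return render(n + len(z) - 1) + ";"


def shared_genes(lists: dict, subset: list[str]) -> tuple[set, pd.DataFrame]:
    """Intersection of the chosen datasets plus all Venn cell counts.

    ``subset`` names 2-5 datasets; returns (shared set, table of all
    2^|subset| - 1 exclusive cell counts keyed by membership pattern).
    """
    unknown = [s for s in subset if s not in lists]
    if unknown:
        raise ValueError(f"unknown dataset names: {unknown}")
    if not 2 <= len(subset) <= 5:
        raise ValueError("subset must name 2-5 datasets")
    sets = {s: set(lists[s]) for s in subset}
    universe = set().union(*sets.values())
    rows = []
    for r in range(1, len(subset) + 1):
        for combo in itertools.combinations(subset, r):
            inside = set.intersection(*[sets[c] for c in combo])
            outside = set().union(*[sets[c] for c in subset if c not in combo]) if r < len(subset) else set()
            cell = inside - outside
            rows.append(
                {"datasets": "&".join(combo), "n_datasets": r, "count": len(cell)}
            )
    shared = set.intersection(*sets.values())
    table = pd.DataFrame(rows)
    assert table["count"].sum() == len(universe)
    return shared, table


def compare_neighbor_sets(neighbor_maps: dict, normalize: bool = True):
    """Compare datasets by the union of their switch genes' neighbor sets.

    ``neighbor_maps`` maps dataset -> {switch gene -> iterable of neighbors}.
    Each dataset is collapsed to its neighbor universe and pushed through
    the same membership / Hamming / dendrogram pipeline as the switch lists.
    Returns (membership, distance matrix, (Z, leaf order, newick)).
    """
    if len(neighbor_maps) < 2:
        raise ValueError("need >= 2 datasets with neighbor maps")
    collapsed = {
        name: set().union(*nm.values()) if nm else set()
        for name, nm in neighbor_maps.items()
    }
    membership = build_membership_matrix(collapsed)
    dist = hamming_distance_matrix(membership, normalize=normalize)
    return membership, dist, cluster_datasets(dist)
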