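"""Node cartography: per-node link statistics, hub classes and switch calls.

Given the correlation graph and a community partition, every non-isolated
node i gets:

* ``k``, ``k_in``, ``k_s``  — total degree, links inside its own community
  C_i, and the vector of links into each community s (sum_s k_s = k);
* ``P = 1 - sum_s (k_s / k)^2``  — participation coefficient, high when
  links spread uniformly over modules, bounded above by 1 - 1/N;
* ``z = (k_in - <k_in>_{C_i}) / sd(k_in)_{C_i}``  — within-module degree,
  a z-score against the *internal*-degree distribution of the module;
* ``K_pi = 1 - (k_in / k)^2``  — clusterphobic coefficient, 0 when all
  links are internal and -> 1 when the node interacts mainly outside its
  community (a purely topological bound, independent of the number of
  modules, unlike P);
* ``z_g = (k_in - <k>_{C_i}) / sd(k)_{C_i}``  — global within-module
  degree, the internal degree scored against the *total*-degree
  distribution of the module;
* ``APCC``  — mean signed Pearson correlation with the node's network
  neighbors (only edges retained by the cutoff count as neighbors).

Since P = K_pi - sum_{s != C_i} (k_s / k)^2, P <= K_pi always, with both
hitting 0 when every link is internal.

Hubs (k >= hub_min_degree, default 5) are classified by APCC: negative ->
fight-club, moderately positive -> date, highly positive -> party.  The
(K_pi, z_g) plane is carved into seven regions R1..R7; switch genes are the
nodes in R4 (K_pi above 0.8, z_g below the hub line) whose APCC is
negative — outward-oriented, non-locally-hubby, anti-correlated with their
partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .community import ClusterAssignment

__all__ = [
    "RegionBounds",
    "community_link_counts",
    "participation_coefficient",
    "within_module_degree",
    "clusterphobic_coefficient",
    "global_within_module_degree",
    "apcc",
    "classify_hubs",
    "assign_region",
    "find_switch_genes",
    "compute_cartography",
]

HUB_MIN_DEGREE = 5
PARTY_THRESHOLD = 0.5


@dataclass(frozen=True)
class RegionBounds:
    """K_pi boundaries of the seven cartography regions.

    Below ``z_cut``: R1 (K_pi <= r1), R2 (<= r2), R3 (<= r3), R4 (> r3);
    at or above ``z_cut``: R5 (K_pi <= r5), R6 (<= r6), R7 (> r6).
    Defaults follow the classic network-cartography role boundaries with
    the R4 edge at 0.8.
    """

    r1: float = 0.05
    r2: float = 0.625
    r3: float = 0.8
    r5: float = 0.3
    r6: float = 0.75
    z_cut: float = 2.5


def community_link_counts(
    g: nx.Graph, ca: ClusterAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count, for every node, its links into each community.

    Returns ``(counts, ks)``: ``counts`` has columns ``k``, ``k_in`` and
    ``community``; ``ks`` is the node x community link-count matrix
    (rows sum to k).  Counts ignore the sign of r.  Unlabeled graph nodes
    are a hard error.
    """
    labels = ca.labels
    missing = [n for n in g.nodes if n not in labels.index]
    if missing:
        raise ValueError(f"graph nodes without community labels: {missing[:10]}")
    nodes = list(g.nodes)
    comms = list(range(1, ca.n_communities + 1))
    pos = {n: i for i, n in enumerate(nodes)}
    lab = labels.loc[nodes].to_numpy()
    mat = np.zeros((len(nodes), ca.n_communities), dtype=int)
    for a, b in g.edges:
        ia, ib = pos[a], pos[b]
        mat[ia, lab[ib] - 1] += 1
        mat[ib, lab[ia] - 1] += 1
    ks = pd.DataFrame(mat, index=pd.Index(nodes), columns=comms)
    k = ks.sum(axis=1)
    own = labels.loc[ks.index]
    k_in = pd.Series(
        ks.to_numpy()[np.arange(len(ks)), own.to_numpy() - 1], index=ks.index
    )
    counts = pd.DataFrame({"k": k, "k_in": k_in, "community": own})
    return counts, ks


def participation_coefficient(ks: pd.DataFrame) -> pd.Series:
    """P = 1 - sum_s (k_s / k)^2 per node; degree-0 nodes are excluded with
    a warning (P is undefined for them)."""
    k = ks.sum(axis=1)
    zero = k.index[k == 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} degree-0 nodes from P")
        ks = ks.drop(index=zero)
        k = k.drop(index=zero)
    frac = ks.div(k, axis=0)
    return (1.0 - (frac**2).sum(axis=1)).rename("P")


def clusterphobic_coefficient(counts: pd.DataFrame) -> pd.Series:
    """K_pi = 1 - (k_in / k)^2 per node; degree-0 nodes excluded."""
    zero = counts.index[counts["k"] == 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} degree-0 nodes from K_pi")
        counts = counts.drop(index=zero)
    return (1.0 - (counts["k_in"] / counts["k"]) ** 2).rename("K_pi")


def _module_zscore(
    values: pd.Series, reference: pd.Series, community: pd.Series, name: str
) -> pd.Series:
    """z-score ``values`` against the per-module distribution of ``reference``
    (population sd); degenerate modules (zero sd) yield 0 with a warning."""
    out = pd.Series(0.0, index=values.index, name=name)
    for c in community.unique():
        members = community.index[community == c]
        ref = reference.loc[members].to_numpy(dtype=float)
        mu, sd = ref.mean(), ref.std()
        if sd == 0:
            warnings.warn(f"module {c}: zero degree sd, {name} set to 0")
            continue
        out.loc[members] = (values.loc[members] - mu) / sd
    return out


def within_module_degree(counts: pd.DataFrame) -> pd.Series:
    """z: internal degree scored against the module's internal-degree stats."""
    return _module_zscore(counts["k_in"], counts["k_in"], counts["community"], "z")


def global_within_module_degree(counts: pd.DataFrame) -> pd.Series:
    """z_g: internal degree scored against the module's *total*-degree stats."""
    return _module_zscore(counts["k_in"], counts["k"], counts["community"], "z_g")


def apcc(g: nx.Graph, nodes=None) -> pd.Series:
    """Averaged Pearson correlation with first neighbors (signed edge r);
    isolated nodes are excluded."""
    nodes = list(g.nodes) if nodes is None else list(nodes)
    out = {}
    for n in nodes:
        rs = [g.edges[n, m]["r"] for m in g.neighbors(n)]
        if rs:
            out[n] = float(np.mean(rs))
    return pd.Series(out, name="APCC")


def classify_hubs(
    k: pd.Series,
    apcc_values: pd.Series,
    hub_min_degree: int = HUB_MIN_DEGREE,
    party_threshold: float = PARTY_THRESHOLD,
) -> pd.Series:
    """Trimodal hub classification by APCC.

    Non-hubs (k < hub_min_degree) -> ``none``; hubs with negative APCC ->
    ``fight-club``; 0 <= APCC < party_threshold -> ``date``;
    APCC >= party_threshold -> ``party``.
    """
    cls = pd.Series("none", index=k.index, name="hub_class")
    hubs = k.index[(k >= hub_min_degree) & k.index.isin(apcc_values.index)]
    a = apcc_values.loc[hubs]
    cls.loc[hubs[a < 0]] = "fight-club"
    cls.loc[hubs[(a >= 0) & (a < party_threshold)]] = "date"
    cls.loc[hubs[a >= party_threshold]] = "party"
    return cls


def assign_region(
    k_pi: pd.Series, z_g: pd.Series, bounds: RegionBounds = RegionBounds()
) -> pd.Series:
    """Map each node to its (K_pi, z_g) cartography region R1..R7."""
    k_pi, z_g = pd.Series(k_pi), pd.Series(z_g)
    region = pd.Series("R1", index=k_pi.index, name="region")
    low = z_g < bounds.z_cut
    region[low & (k_pi > bounds.r1)] = "R2"
    region[low & (k_pi > bounds.r2)] = "R3"
    region[low & (k_pi > bounds.r3)] = "R4"
    region[~low] = "R5"
    region[~low & (k_pi > bounds.r5)] = "R6"
    region[~low & (k_pi > bounds.r6)] = "R7"
    return region


def find_switch_genes(
    table: pd.DataFrame,
    g: nx.Graph | None = None,
    require_hub: bool = False,
    hub_min_degree: int = HUB_MIN_DEGREE,
) -> tuple[list, dict]:
    """Call switch genes: region R4 with negative APCC.

    ``require_hub=True`` additionally demands k >= hub_min_degree (switch
    genes as a subset of fight-club hubs).  Returns the sorted gene list and,
    when the graph is given, each switch gene's first-neighbor set.
    """
    mask = (table["region"] == "R4") & (table["APCC"] < 0)
    if require_hub:
        mask &= table["k"] >= hub_min_degree
    switches = sorted(table.index[mask])
    neighbors = (
        {s: sorted(g.neighbors(s)) for s in switches} if g is not None else {}
    )
    return switches, neighbors


def compute_cartography(
    g: nx.Graph,
    ca: ClusterAssignment,
    hub_min_degree: int = HUB_MIN_DEGREE,
    party_threshold: float = PARTY_THRESHOLD,
    bounds: RegionBounds = RegionBounds(),
    require_hub_for_switch: bool = False,
) -> pd.DataFrame:
    """Assemble the full per-node cartography table.

    Isolated nodes are dropped (their P, K_pi and APCC are undefined) —
    they remain visible through the graph's ``isolated`` node flag.
    Columns: k, k_in, community, P, z, K_pi, z_g, APCC, region, hub,
    hub_class, switch.
    """
    live = [n for n in g.nodes if g.degree(n) > 0]
    if not live:
        raise ValueError("graph has no edges; nothing to map")
    sub = g.subgraph(live)
    counts, ks = community_link_counts(sub, ca)
    table = counts.copy()
    table["P"] = participation_coefficient(ks)
    table["z"] = within_module_degree(counts)
    table["K_pi"] = clusterphobic_coefficient(counts)
    table["z_g"] = global_within_module_degree(counts)
    table["APCC"] = apcc(sub)
    table["region"] = assign_region(table["K_pi"], table["z_g"], bounds)
    table["hub"] = table["k"] >= hub_min_degree
    table["hub_class"] = classify_hubs(
        table["k"], table["APCC"], hub_min_degree, party_threshold
    )
    switches, _ = find_switch_genes(
        table, require_hub=require_hub_for_switch, hub_min_degree=hub_min_degree
    )
    table["switch"] = table.index.isin(switches)
    return table
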