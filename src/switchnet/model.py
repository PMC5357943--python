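"""The SwitchMiner model: expression matrix in, switch genes out.

``SwitchMiner`` bundles the full procedure — optional low-expression and
differential filtering, correlation-network construction, correlation-
distance community detection, (K_pi, z_g) cartography with APCC hub
classes, and switch-gene calling — behind a statsmodels-style
``model.fit() -> results`` interface.  Robustness curves, survival ranking
and the diagnostic plots hang off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import networkx as nx

from . import cartography as carto
from . import community as comm
from . import io as eio
from . import network as net
from . import robustness as rob
from . import survival as surv
from ._utils import config_hash

__all__ = ["SwitchMiner", "SwitchMinerResults"]


class SwitchMiner:
    """Switch-gene detection model for one expression dataset.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples matrix.  If it carries tumor/normal annotations the
        network is built from the tumor samples of the differentially
        expressed genes; otherwise all genes and samples are used directly.
    cutoff : float
        Absolute-correlation threshold for network edges (default 0.8).
    k : int or None
        Number of communities; ``None`` selects k by the elbow rule over
        ``k_range``.
    seed : int
        Master seed for clustering restarts and k selection (mandatory for
        reproducibility).
    """

    def __init__(
        self,
        expression: eio.ExpressionMatrix,
        *,
        cutoff: float = 0.8,
        k: int | None = None,
        k_range: tuple[int, int] = (2, 10),
        seed: int = 0,
        restarts: int = 10,
        elbow_tol: float = 0.05,
        hub_min_degree: int = carto.HUB_MIN_DEGREE,
        party_threshold: float = carto.PARTY_THRESHOLD,
        region_bounds: carto.RegionBounds = carto.RegionBounds(),
        de_log2fc: float = 1.0,
        de_pseudocount: float = 0.05,
        min_value: float | None = None,
        min_fraction: float = 0.8,
        network_condition: str = "tumor",
        require_hub_for_switch: bool = False,
    ) -> None:
        self.expression = expression
        self.params: dict[str, Any] = dict(
            cutoff=cutoff, k=k, k_range=k_range, seed=seed, restarts=restarts,
            elbow_tol=elbow_tol, hub_min_degree=hub_min_degree,
            party_threshold=party_threshold, region_bounds=region_bounds,
            de_log2fc=de_log2fc, de_pseudocount=de_pseudocount,
            min_value=min_value, min_fraction=min_fraction,
            network_condition=network_condition,
            require_hub_for_switch=require_hub_for_switch,
        )

    @classmethod
    def from_files(
        cls, expression_path, sample_sheet_path=None, **kwargs
    ) -> "SwitchMiner":
        em = eio.read_expression(expression_path)
        if sample_sheet_path is not None:
            em = eio.ExpressionMatrix(em.values, eio.read_sample_sheet(sample_sheet_path))
        return cls(em, **kwargs)

    def fit(self) -> "SwitchMinerResults":
        p = self.params
        em = self.expression
        stage_counts = {"genes_input": em.n_genes, "samples_input": em.n_samples}

        if p["min_value"] is not None:
            em = eio.filter_low_expression(em, p["min_value"], p["min_fraction"])
        stage_counts["genes_after_filter"] = em.n_genes

        de_table = None
        if em.has_conditions:
            de_table = eio.select_differential(em, p["de_log2fc"], p["de_pseudocount"])
            de_genes = de_table.index[de_table["selected"]]
            if len(de_genes) < 3:
                raise ValueError(
                    f"only {len(de_genes)} differential genes at "
                    f"|log2FC| >= {p['de_log2fc']}; lower the threshold"
                )
            em_net = em.subset_genes(de_genes).subset_samples(
                em.condition_samples(p["network_condition"])
            )
        else:
            em_net = em
        stage_counts["genes_in_network"] = em_net.n_genes

        corr = net.pearson_matrix(em_net)
        graph = net.build_graph(corr, p["cutoff"])
        stage_counts["edges"] = graph.number_of_edges()
        isolated = [n for n, d in graph.nodes(data=True) if d.get("isolated")]
        stage_counts["isolated_nodes"] = len(isolated)

        k = p["k"]
        if k is None:
            k = comm.choose_k(
                em_net, p["k_range"], seed=p["seed"],
                tol=p["elbow_tol"], restarts=p["restarts"],
            )
        assignment = comm.cluster_expression(
            em_net, k, seed=p["seed"], restarts=p["restarts"]
        )
        stage_counts["communities"] = assignment.n_communities

        table = carto.compute_cartography(
            graph, assignment,
            hub_min_degree=p["hub_min_degree"],
            party_threshold=p["party_threshold"],
            bounds=p["region_bounds"],
            require_hub_for_switch=p["require_hub_for_switch"],
        )
        switches, neighbor_sets = carto.find_switch_genes(
            table, graph,
            require_hub=p["require_hub_for_switch"],
            hub_min_degree=p["hub_min_degree"],
        )
        stage_counts["hubs"] = int(table["hub"].sum())
        stage_counts["switch_genes"] = len(switches)

        return SwitchMinerResults(
            model=self, expression_used=em_net, de_table=de_table, corr=corr,
            graph=graph, assignment=assignment, cartography=table,
            switch_genes=switches, neighbor_sets=neighbor_sets,
            isolated_genes=isolated, stage_counts=stage_counts,
        )


@dataclass
class SwitchMinerResults:
    """Fitted pipeline state: network, partition, cartography, switch calls."""

    model: SwitchMiner
    expression_used: eio.ExpressionMatrix
    de_table: pd.DataFrame | None
    corr: pd.DataFrame
    graph: nx.Graph
    assignment: comm.ClusterAssignment
    cartography: pd.DataFrame
    switch_genes: list
    neighbor_sets: dict
    isolated_genes: list
    stage_counts: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        return self.model.params

    @property
    def config_hash(self) -> str:
        return config_hash(self.params)

    def hub_counts(self) -> pd.Series:
        return self.cartography["hub_class"].value_counts()

    def summary(self) -> str:
        """Human-readable run summary (counts at each stage, hub classes,
        switch genes)."""
        c = self.stage_counts
        hubs = self.hub_counts()
        lines = [
            "SwitchMiner results",
            "===================",
            f"genes in              {c.get('genes_input', '-')}",
            f"samples in            {c.get('samples_input', '-')}",
            f"genes in network      {c.get('genes_in_network', '-')}",
            f"edges (|r| >= {self.params['cutoff']})    {c.get('edges', '-')}",
            f"isolated nodes        {c.get('isolated_nodes', '-')}",
            f"communities           {c.get('communities', '-')}",
            f"hubs (k >= {self.params['hub_min_degree']})          {c.get('hubs', '-')}",
            f"  party / date / fight-club: "
            f"{hubs.get('party', 0)} / {hubs.get('date', 0)} / {hubs.get('fight-club', 0)}",
            f"switch genes          {len(self.switch_genes)}",
        ]
        if self.switch_genes:
            shown = ", ".join(map(str, self.switch_genes[:10]))
            more = "" if len(self.switch_genes) <= 10 else f" … (+{len(self.switch_genes) - 10})"
            lines.append(f"  {shown}{more}")
        lines.append(f"config hash           {self.config_hash}")
        return "\n".join(lines)

    # -- downstream analyses -------------------------------------------------
    def robustness(
        self, fractions=(0.05, 0.10, 0.15, 0.20, 0.25),
        n_random_reps: int = 20, seed: int | None = None,
        pair_convention: str = "connected",
    ) -> pd.DataFrame:
        """Targeted-vs-random removal curves on the fitted network."""
        live = self.graph.subgraph(
            [n for n in self.graph if self.graph.degree(n) > 0]
        ).copy()
        return rob.compare_strategies(
            live, self.cartography, fractions,
            n_random_reps=n_random_reps,
            seed=self.params["seed"] if seed is None else seed,
            pair_convention=pair_convention,
        )

    def rank_survival(
        self, clinical: eio.ClinicalTable, genes=None, **kwargs
    ) -> tuple[pd.DataFrame, list]:
        """Log-rank prioritization of (by default) the called switch genes."""
        genes = self.switch_genes if genes is None else genes
        em = self.model.expression
        if em.samples is None:
            raise ValueError("survival ranking needs tumor/normal sample annotations")
        return surv.rank_switch_genes_by_survival(em, clinical, genes, **kwargs)

    # -- plotting ------------------------------------------------------------
    def plot_apcc_distribution(self, path=None):
        from .plots import plot_apcc_distribution
        return plot_apcc_distribution(self.cartography, path=path)

    def plot_cartography(self, path=None):
        from .plots import plot_heat_cartography
        return plot_heat_cartography(
            self.cartography, bounds=self.params["region_bounds"], path=path
        )

    def plot_degree_distribution(self, path=None):
        from .plots import plot_degree_distribution
        from .network import degree_summary
        hist, _ = degree_summary(self.graph)
        return plot_degree_distribution(hist, path=path)
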