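import numpy as np
import pandas as pd
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchnet import (
    ClusterAssignment,
    apcc,
    assign_region,
    classify_hubs,
    clusterphobic_coefficient,
    community_link_counts,
    compute_cartography,
    find_switch_genes,
    global_within_module_degree,
    participation_coefficient,
    within_module_degree,
)
from oracles import brute_cartography, brute_link_counts


def random_partitioned_graph(n, p, n_comm, seed):
    """ER graph with random signed edge correlations and a random partition."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    for a, b in g.edges:
        r = rng.uniform(0.5, 1.0) * rng.choice([-1, 1])
        g.edges[a, b]["r"] = float(r)
    labels = rng.integers(1, n_comm + 1, size=n)
    # compact to 1..N with every label used
    uniq = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    series = pd.Series([uniq[l] for l in labels], index=list(g.nodes))
    ca = ClusterAssignment(series, n_communities=len(uniq), quality=float("nan"))
    return g, ca


def counts_frame(k, k_in, community=1):
    idx = range(len(k))
    return pd.DataFrame({"k": k, "k_in": k_in, "community": community}, index=idx)


class TestLinkCounts:
    def test_all_internal(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.9, "r")
        ca = ClusterAssignment(pd.Series(1, index=list(g)), 1, 0.0)
        counts, ks = community_link_counts(g, ca)
        assert (counts["k"] == 4).all() and (counts["k_in"] == 4).all()
        assert (ks.sum(axis=1) == counts["k"]).all()

    def test_bridge_node_splits_two_two(self):
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (0, 4)])
        labels = pd.Series({0: 1, 1: 1, 2: 1, 3: 2, 4: 2})
        ca = ClusterAssignment(labels, 2, 0.0)
        _, ks = community_link_counts(g, ca)
        assert list(ks.loc[0]) == [2, 2]

    def test_unlabeled_node_is_hard_error(self):
        g = nx.path_graph(3)
        ca = ClusterAssignment(pd.Series({0: 1, 1: 1}, dtype=int), 1, 0.0)
        with pytest.raises(ValueError, match="without community"):
            community_link_counts(g, ca)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_enumeration_oracle(self, seed):
        g, ca = random_partitioned_graph(24, 0.2, 4, seed)
        counts, ks = community_link_counts(g, ca)
        oracle = brute_link_counts(g, ca.labels.to_dict())
        for n in g.nodes:
            k, k_in, per = oracle[n]
            assert counts.loc[n, "k"] == k and counts.loc[n, "k_in"] == k_in
            for c in ks.columns:
                assert ks.loc[n, c] == per.get(c, 0)


class TestCoefficients:
    def test_participation_single_module_is_zero(self):
        ks = pd.DataFrame({1: [7], 2: [0]})
        assert participation_coefficient(ks)[0] == pytest.approx(0.0)

    def test_participation_uniform_over_five_modules(self):
        # 20 links spread 4/4/4/4/4: the N=5 supremum 1 - 1/5
        ks = pd.DataFrame([[4, 4, 4, 4, 4]])
        assert participation_coefficient(ks)[0] == pytest.approx(0.8)

    def test_participation_six_four_split(self):
        ks = pd.DataFrame([[6, 4]])
        assert participation_coefficient(ks)[0] == pytest.approx(0.48)

    def test_clusterphobic_extremes_and_midpoint(self):
        counts = counts_frame(k=[5, 10, 10], k_in=[5, 0, 5])
        k_pi = clusterphobic_coefficient(counts)
        assert k_pi.tolist() == pytest.approx([0.0, 1.0, 0.75])

    def test_within_module_degree_centering(self):
        # internal degrees (1,1,2,3,3): mean 2, population sd sqrt(0.8)
        counts = counts_frame(k=[3, 3, 3, 4, 4], k_in=[1, 1, 2, 3, 3])
        z = within_module_degree(counts)
        assert z[2] == pytest.approx(0.0)
        assert z[3] == pytest.approx(1.0 / np.sqrt(0.8))

    def test_degenerate_module_gives_zero_z(self):
        counts = counts_frame(k=[4, 5], k_in=[2, 2])
        with pytest.warns(UserWarning, match="zero degree sd"):
            z = within_module_degree(counts)
        assert (z == 0).all()

    def test_global_within_module_degree_uses_total_stats(self):
        # totals (4,6): mean 5, pop sd 1; node internal degrees (2,3)
        counts = counts_frame(k=[4, 6], k_in=[2, 3])
        z_g = global_within_module_degree(counts)
        assert z_g.tolist() == pytest.approx([-3.0, -2.0])
        assert (z_g < 0).all()  # internal below every total degree


class TestApcc:
    def test_mean_of_neighbor_correlations(self):
        g = nx.star_graph(3)
        for (a, b), r in zip(g.edges, (-0.9, -0.8, -0.7)):
            g.edges[a, b]["r"] = r
        assert apcc(g)[0] == pytest.approx(-0.8)

    def test_single_neighbor_identity(self):
        g = nx.Graph([(0, 1, {"r": 0.95})])
        assert apcc(g)[1] == pytest.approx(0.95)

    def test_isolated_node_excluded(self):
        g = nx.Graph([(0, 1, {"r": 0.9})])
        g.add_node(2)
        assert 2 not in apcc(g).index


class TestClassification:
    def test_examples(self):
        k = pd.Series({"a": 4, "b": 10, "c": 10})
        a = pd.Series({"a": -0.9, "b": -0.3, "c": 0.9})
        cls = classify_hubs(k, a, hub_min_degree=5, party_threshold=0.5)
        assert cls.tolist() == ["none", "fight-club", "party"]

    def test_date_band(self):
        cls = classify_hubs(pd.Series([8]), pd.Series([0.2]))
        assert cls[0] == "date"

    def test_regions(self):
        k_pi = pd.Series([0.9, 0.0, 0.9, 0.05, 0.4, 0.7])
        z_g = pd.Series([1.0, 0.0, 3.0, 1.0, 0.5, 2.5])
        regions = assign_region(k_pi, z_g)
        assert regions.tolist() == ["R4", "R1", "R7", "R1", "R2", "R6"]

    def test_switch_rule(self):
        table = pd.DataFrame(
            {"region": ["R4", "R4", "R2"], "APCC": [-0.4, 0.1, -0.9], "k": [9, 9, 9]},
            index=["s", "x", "y"],
        )
        switches, _ = find_switch_genes(table)
        assert switches == ["s"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_statistics_match_brute_force(self, seed):
        g, ca = random_partitioned_graph(28, 0.18, 4, 100 + seed)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        table = compute_cartography(g, ca)
        oracle = brute_cartography(g, ca.labels.to_dict())
        for n, row in oracle.items():
            for col in ("k", "k_in", "P", "z", "K_pi", "z_g", "APCC"):
                assert table.loc[n, col] == pytest.approx(row[col], abs=1e-10), (n, col)
        assert (table["P"] <= table["K_pi"] + 1e-12).all()

    def test_invariant_under_community_relabeling(self):
        g, ca = random_partitioned_graph(25, 0.2, 3, 77)
        table = compute_cartography(g, ca)
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = ClusterAssignment(
            ca.labels.map(perm), ca.n_communities, ca.quality
        )
        table2 = compute_cartography(g, relabeled)
        for col in ("P", "z", "K_pi", "z_g", "APCC"):
            np.testing.assert_allclose(table[col], table2[col], atol=1e-12)
        for col in ("region", "hub_class", "switch"):
            assert (table[col] == table2[col]).all()


class TestParticipationBounds:
    @given(
        ks=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=6)
        .filter(lambda v: sum(v) > 0)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_p_bounded_by_k_pi_and_module_count(self, ks):
        frame = pd.DataFrame([ks])
        counts = counts_frame(k=[sum(ks)], k_in=[ks[0]])
        p = participation_coefficient(frame)[0]
        k_pi = clusterphobic_coefficient(counts)[0]
        assert p <= k_pi + 1e-12
        assert p <= 1 - 1 / len(ks) + 1e-12
        if sum(ks) == ks[0]:  # all links internal: common lower bound
            assert p == pytest.approx(0.0) and k_pi == pytest.approx(0.0)
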