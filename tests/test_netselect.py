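import numpy as np
import pytest

from micronet import (
    CompositeWeights,
    UndirectedNetwork,
    canonical_edge,
    centralities,
    finalize_selection,
    strategy1_differential,
    strategy2_composite,
    strategy2_consensus,
)
from micronet.netselect import top_fraction

import pandas as pd


def path_graph():
    return UndirectedNetwork(["a", "b", "c"], {("a", "b"), ("b", "c")})


def star_graph(n_leaves=4):
    leaves = [f"l{k}" for k in range(n_leaves)]
    return UndirectedNetwork(
        ["hub"] + leaves, {canonical_edge("hub", l) for l in leaves}
    )


class TestCentralities:
    def test_path_graph_values(self):
        m = centralities(path_graph()).metrics
        assert m["degree"].tolist() == [1, 2, 1]
        assert m["betweenness"].tolist() == [0.0, 1.0, 0.0]

    def test_edgeless_graph(self):
        m = centralities(UndirectedNetwork(["a", "b", "c"])).metrics
        assert (m["degree"] == 0).all()
        assert (m["closeness"] == 0).all()
        assert (m["eigenvector"] == 0).all()

    def test_star_center(self):
        m = centralities(star_graph()).metrics
        assert m.loc["hub", "degree"] == 4
        assert m.loc["hub", "betweenness"] == pytest.approx(1.0)  # all 6 leaf pairs

    def test_pagerank_sums_to_one(self, rng):
        from conftest import random_network

        net = random_network([f"n{k}" for k in range(10)], 0.3, rng)
        m = centralities(net).metrics
        assert m["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(m.to_numpy()).all()

    def test_harmonic_closeness_on_path(self):
        m = centralities(path_graph()).metrics
        # a: 1/1 + 1/2 = 1.5 over (n-1)=2
        assert m.loc["a", "closeness"] == pytest.approx(0.75)
        assert m.loc["b", "closeness"] == pytest.approx(1.0)

    def test_empty_node_set_errors(self):
        with pytest.raises(ValueError):
            centralities(UndirectedNetwork([]))


class TestTopFraction:
    def test_exact_size(self):
        s = pd.Series(np.arange(10.0), index=[f"t{k}" for k in range(10)])
        assert top_fraction(s, 0.2) == {"t8", "t9"}

    def test_tie_expansion_warns(self):
        s = pd.Series([5.0, 5.0, 5.0, 1.0], index=list("abcd"))
        with pytest.warns(UserWarning, match="tie"):
            chosen = top_fraction(s, 0.25)
        assert chosen == {"a", "b", "c"}


class TestStrategy2:
    def test_star_center_scores_one(self):
        scores, top = strategy2_composite(star_graph())
        assert scores["hub"] == pytest.approx(1.0)  # every scaled metric is 1
        assert "hub" in top
        leaves = scores.drop("hub")
        assert leaves.nunique() == 1  # symmetric ties

    def test_degree_only_weights_reduce_to_degree_ranking(self, rng):
        from conftest import random_network

        net = random_network([f"n{k}" for k in range(12)], 0.4, rng)
        w = CompositeWeights(1, 0, 0, 0, 0)
        scores, _ = strategy2_composite(net, w)
        deg = centralities(net).metrics["degree"]
        assert np.array_equal(np.argsort(scores.values), np.argsort(deg.values))

    def test_uniform_weights_on_vertex_transitive_graph(self):
        # a cycle is vertex-transitive: every node must score identically
        nodes = [f"n{k}" for k in range(6)]
        edges = {canonical_edge(nodes[k], nodes[(k + 1) % 6]) for k in range(6)}
        net = UndirectedNetwork(nodes, edges)
        w = CompositeWeights(*([0.2] * 5))
        with pytest.warns(UserWarning):  # constant metrics contribute 0
            scores, _ = strategy2_composite(net, w)
        assert scores.nunique() == 1

    def test_consensus_intersections(self):
        nets_a = {"m1": star_graph(), "m2": star_graph()}
        both = strategy2_consensus(nets_a, nets_a)
        assert "hub" in both["clean"] and both["clean"] == both["scab"]
        assert both["intersection"] == both["clean"]


class TestStrategy1:
    def make_condition_pair(self):
        """one taxon's connectivity collapses in the scab network"""
        nodes = [f"t{k}" for k in range(10)]
        hub_edges = {canonical_edge("t0", n) for n in nodes[1:6]}
        background = {canonical_edge("t8", "t9"), canonical_edge("t6", "t7")}
        clean = UndirectedNetwork(nodes, hub_edges | background)
        scab = UndirectedNetwork(nodes, background)
        return clean, scab

    def test_collapsing_hub_selected_by_all_methods(self):
        clean, scab = self.make_condition_pair()
        selected, table = strategy1_differential(
            {"m1": clean, "m2": clean}, {"m1": scab, "m2": scab}
        )
        assert "t0" in selected
        assert table.loc["t0", "selected"]
        assert "m1:degree" in table.loc["t0", "features"]

    def test_identical_conditions_warn_degenerate(self):
        clean, _ = self.make_condition_pair()
        with pytest.warns(UserWarning, match="zero"):
            selected, _ = strategy1_differential({"m": clean}, {"m": clean})

    def test_intersection_across_methods(self):
        clean, scab = self.make_condition_pair()
        # second method sees no difference anywhere except t9
        nodes = list(clean.node_ids)
        alt_clean = UndirectedNetwork(nodes, {canonical_edge("t8", "t9")})
        alt_scab = UndirectedNetwork(nodes, set())
        with pytest.warns(UserWarning):
            selected, _ = strategy1_differential(
                {"m1": clean, "m2": alt_clean}, {"m1": scab, "m2": alt_scab}
            )
        # only taxa flagged by BOTH methods survive
        sel_m1, _ = strategy1_differential({"m1": clean}, {"m1": scab})
        with pytest.warns(UserWarning):
            sel_m2, _ = strategy1_differential({"m2": alt_clean}, {"m2": alt_scab})
        assert selected == sel_m1 & sel_m2

    def test_taxa_mismatch_errors(self):
        clean, scab = self.make_condition_pair()
        other = UndirectedNetwork(["x", "y"])
        with pytest.raises(ValueError):
            strategy1_differential({"m": clean}, {"m": other})


class TestFinalize:
    def test_tiers_match_set_algebra(self):
        taxa = list("abcdefg")
        ml, s1, s2 = {"a", "b", "c", "e"}, {"a", "b", "d"}, {"a", "c", "d"}
        rep = finalize_selection(taxa, ml, s1, s2)
        assert rep.tiers["a"] == ml & s1 & s2
        assert rep.tiers["b"] == (ml & s1) - s2
        assert rep.tiers["c"] == (ml & s2) - s1
        assert rep.tiers["d"] == (s1 & s2) - ml
        assert rep.final_selected == {"a"}

    def test_ml_and_any_network_rule(self):
        rep = finalize_selection(
            list("abcd"), {"a", "b"}, {"b"}, {"c"}, rule="ml_and_any_network"
        )
        assert rep.final_selected == {"b"}

    def test_unselected_taxon(self):
        rep = finalize_selection(["a", "b"], {"a"}, {"a"}, {"a"})
        assert "b" not in rep.final_selected
        assert not rep.to_frame().loc["b"].any()

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="universe"):
            finalize_selection(["a"], {"z"}, set(), set())

    def test_relabeling_invariance(self):
        taxa = list("abcd")
        ml, s1, s2 = {"a", "b"}, {"b", "c"}, {"b", "d"}
        rep = finalize_selection(taxa, ml, s1, s2)
        ren = {t: t.upper() for t in taxa}
        rep2 = finalize_selection(
            [ren[t] for t in taxa],
            {ren[t] for t in ml},
            {ren[t] for t in s1},
            {ren[t] for t in s2},
        )
        assert {ren[t] for t in rep.final_selected} == rep2.final_selected
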