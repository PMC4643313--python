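"""Network reduction and per-stage activity projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineagetx as lx
from lineagetx.containers import Edge, InteractionNetwork
from lineagetx.network import network_from_edges


@pytest.fixture()
def toy_net():
    return network_from_edges(
        [
            ("Pou5f1", "Nanog", "activates"),
            ("Nanog", "Sox2", "activates"),
            ("Tcf7l1", "Nanog", "inhibits"),
            ("Sox2", "Pou5f1", "activates"),
        ],
        extra_nodes=["Klf4"],
    )


@pytest.fixture()
def toy_rel():
    # gene x stage relative expression (rows centered)
    data = {
        "Pou5f1": [0.5, 0.5, -1.0],
        "Nanog": [-0.2, 0.4, -0.2],
        "Sox2": [0.3, 0.3, -0.6],
        "Tcf7l1": [-1.0, -1.0, 2.0],
        "Klf4": [0.0, 0.0, 0.0],
    }
    return pd.DataFrame(data, index=["s1", "s2", "s3"]).T


class TestReduceNetwork:
    def test_full_dynamic_set_is_identity(self, toy_net):
        out = lx.reduce_network(toy_net, set(toy_net.nodes))
        assert out.nodes == toy_net.nodes - {"Klf4"}  # Klf4 isolated, not an anchor
        assert out.edges == toy_net.edges

    def test_disjoint_dynamic_set_leaves_anchors(self, toy_net):
        out = lx.reduce_network(toy_net, {"Gata6"}, anchors={"Pou5f1", "Nanog", "Sox2"})
        assert out.nodes == frozenset({"Pou5f1", "Nanog", "Sox2"})
        assert all(e.source in out.nodes and e.target in out.nodes for e in out.edges)

    def test_case_insensitive_matching(self, toy_net):
        out = lx.reduce_network(toy_net, {"POU5F1", "nanog", "SOX2", "tcf7l1"})
        assert out.nodes == frozenset({"Pou5f1", "Nanog", "Sox2", "Tcf7l1"})

    def test_isolated_anchor_retained(self):
        net = network_from_edges([("A", "B", "activates")], extra_nodes=["Nanog"])
        out = lx.reduce_network(net, {"A", "B"})
        assert "Nanog" in out.nodes

    def test_empty_intersection_raises(self, toy_net):
        with pytest.raises(ValueError, match="no network node"):
            lx.reduce_network(toy_net, {"Gata6"}, anchors={"Foxa2"})

    def test_planted_counts(self, sim_small):
        cfg, em, truth = sim_small
        net = lx.simulate_network(cfg, truth, n_nodes=12, edge_density=0.3)
        dyn = set(truth.dynamic_flag.index[truth.dynamic_flag])
        assert set(net.nodes) <= dyn
        reduced = lx.reduce_network(net, dyn, anchors=set(), keep_isolated=True)
        assert reduced.nodes == net.nodes


class TestNodeActivity:
    def test_positive_relative_expression_is_active(self, toy_net, toy_rel):
        active = lx.node_activity(toy_rel, "s1", toy_net)
        assert "Pou5f1" in active and "Sox2" in active
        assert "Nanog" not in active and "Tcf7l1" not in active

    def test_exact_zero_is_inactive(self, toy_net, toy_rel):
        active = lx.node_activity(toy_rel, "s1", toy_net)
        assert "Klf4" not in active  # flat gene, rel expr exactly 0

    def test_missing_gene_inactive_everywhere(self, toy_rel):
        net = network_from_edges([("Pou5f1", "Zfp42", "activates")])
        for stage in toy_rel.columns:
            assert "Zfp42" not in lx.node_activity(toy_rel, stage, net)

    def test_unknown_stage_rejected(self, toy_net, toy_rel):
        with pytest.raises(ValueError, match="unknown stage"):
            lx.node_activity(toy_rel, "s9", toy_net)


class TestActiveEdges:
    def test_both_endpoints_required(self, toy_net):
        edges = lx.active_edges(toy_net, {"Pou5f1", "Nanog"})
        assert edges == frozenset({Edge("Pou5f1", "Nanog", "activates")})
        # one endpoint active -> inactive edge
        assert lx.active_edges(toy_net, {"Nanog"}) == frozenset()

    def test_empty_active_set(self, toy_net):
        assert lx.active_edges(toy_net, set()) == frozenset()

    def test_monotone_in_active_set(self, toy_net):
        small = lx.active_edges(toy_net, {"Pou5f1", "Nanog"})
        large = lx.active_edges(toy_net, {"Pou5f1", "Nanog", "Sox2"})
        assert small <= large


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_edge_activity_closure_property(seed):
    """For random networks and random active sets, the active edge set is
    exactly {e : source and target active}."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(8)]
    edges = [
        (a, b, rng.choice(["activates", "inhibits"]))
        for a in nodes
        for b in nodes
        if a != b and rng.random() < 0.3
    ]
    net = network_from_edges(edges, extra_nodes=nodes)
    active = {n for n in nodes if rng.random() < 0.5}
    got = lx.active_edges(net, active)
    want = frozenset(e for e in net.edges if e.source in active and e.target in active)
    assert got == want


class TestConnectivityProfile:
    def test_planted_peak_stage_recovered(self, sim_small):
        cfg, em, truth = sim_small
        net = lx.simulate_network(cfg, truth, n_nodes=12, edge_density=0.25)
        sf = lx.size_factors(em.counts)
        em.fpkm = lx.fpkm(em)
        rel = lx.scale_to_stage_mean(em.fpkm, em.stage_of())
        prof = lx.connectivity_profile(net, rel)
        assert prof.index[prof["is_peak"]][0] == truth.peak_stage

    def test_flat_expression_gives_no_activity(self, toy_net):
        rel = pd.DataFrame(
            0.0, index=["Pou5f1", "Nanog", "Sox2", "Tcf7l1"], columns=["s1", "s2"]
        )
        prof = lx.connectivity_profile(toy_net, rel)
        assert (prof["n_active_nodes"] == 0).all()
        assert (prof["n_active_edges"] == 0).all()

    def test_all_positive_stage_activates_all_edges(self, toy_net):
        rel = pd.DataFrame(
            {"s1": [1.0, 1.0, 1.0, 1.0], "s2": [-1.0, -1.0, -1.0, -1.0]},
            index=["Pou5f1", "Nanog", "Sox2", "Tcf7l1"],
        )
        prof = lx.connectivity_profile(toy_net, rel)
        assert prof.loc["s1", "n_active_edges"] == toy_net.n_edges

    def test_centered_genes_active_somewhere_inactive_somewhere(self, sim_small):
        _, em, _ = sim_small
        em.fpkm = lx.fpkm(em)
        rel = lx.scale_to_stage_mean(em.fpkm, em.stage_of())
        varying = rel.loc[rel.std(axis=1) > 0]
        assert ((varying > 0).any(axis=1)).all()
        assert ((varying <= 0).any(axis=1)).all()


class TestCoreCoexpression:
    def test_planted_single_stage(self):
        fpkm = pd.DataFrame(
            {"m": [50.0, 50.0], "icm": [5.0, 50.0], "epi": [50.0, 50.0], "post": [5.0, 5.0]},
            index=["Nanog", "Esrrb"],
        )
        assert lx.core_coexpression_stages(fpkm, ["Nanog", "Esrrb"], floor=10) == {"m", "epi"}
        fpkm.loc["Nanog", "m"] = 5.0
        assert lx.core_coexpression_stages(fpkm, ["Nanog", "Esrrb"], floor=10) == {"epi"}

    def test_floor_above_max_gives_empty_set(self):
        fpkm = pd.DataFrame({"a": [3.0], "b": [4.0]}, index=["g"])
        assert lx.core_coexpression_stages(fpkm, ["g"], floor=100) == set()

    def test_zero_floor_with_expression_everywhere(self):
        fpkm = pd.DataFrame({"a": [3.0], "b": [4.0]}, index=["g"])
        assert lx.core_coexpression_stages(fpkm, ["g"], floor=0) == {"a", "b"}

    def test_missing_core_gene_listed(self):
        fpkm = pd.DataFrame({"a": [3.0]}, index=["g"])
        with pytest.raises(ValueError, match="Erk1"):
            lx.core_coexpression_stages(fpkm, ["g", "Erk1"], floor=0)

    def test_empty_core_rejected(self):
        fpkm = pd.DataFrame({"a": [3.0]}, index=["g"])
        with pytest.raises(ValueError, match="empty"):
            lx.core_coexpression_stages(fpkm, [], floor=0)


class TestSimulateNetwork:
    def test_complete_density_edge_count(self, sim_small):
        cfg, _, truth = sim_small
        net = lx.simulate_network(cfg, truth, n_nodes=4, edge_density=1.0)
        assert net.n_edges == 12
        assert not any(e.source == e.target for e in net.edges)

    def test_invalid_density_rejected(self, sim_small):
        cfg, _, truth = sim_small
        with pytest.raises(ValueError, match="edge_density"):
            lx.simulate_network(cfg, truth, n_nodes=4, edge_density=0.0)

    def test_planted_profiles_active_at_peak(self, sim_small):
        """End to end: the planted node profiles, projected through the
        activity rule, are all active at the recorded peak stage."""
        cfg, _, truth = sim_small
        net = lx.simulate_network(cfg, truth, n_nodes=12, edge_density=0.5)
        rel = lx.scale_to_stage_mean(truth.stage_mean)
        active = lx.node_activity(rel, truth.peak_stage, net)
        assert active == net.nodes
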