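"""Network alignment: node scoring, greedy optimisation, EC/SS, alpha scan."""

import numpy as np
import pandas as pd
import pytest

from occnet.containers import (
    AlignmentResult,
    CooccurrenceNetwork,
    SeqSimilarityMatrix,
    ValidationError,
)
from occnet.alignment import (
    align,
    alignment_scores,
    alignment_scores_from_mapping,
    alpha_scan,
    compare_to_random,
    hiveplot_export,
    node_score,
    pairwise_identity,
)


def _net(edges, isolated=()):
    net = CooccurrenceNetwork()
    for n in sorted({x for e in edges for x in e} | set(isolated)):
        net.add_otu_node(n)
    for u, v in edges:
        net.add_edge(u, v, sign="copresence")
    return net


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        mat = pairwise_identity({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert mat.identity.at["a", "b"] == pytest.approx(1.0)

    def test_single_mismatch_length_four(self):
        mat = pairwise_identity({"a": "ACGT", "b": "ACGA"})
        assert mat.identity.at["a", "b"] == pytest.approx(0.75)

    def test_symmetric_unit_diagonal(self):
        mat = pairwise_identity({"a": "ACGTAC", "b": "ACTTAC", "c": "TTGTAC"})
        arr = mat.identity.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            pairwise_identity({"a": "", "b": "ACGT"})


class TestNodeScore:
    def test_alpha_extremes(self):
        assert node_score("u", "v", 1.0, 0.8, 0.4) == pytest.approx(0.8)
        assert node_score("u", "v", 0.0, 0.8, 0.4) == pytest.approx(0.4)

    def test_midpoint_arithmetic(self):
        assert node_score("u", "v", 0.5, 0.8, 0.4) == pytest.approx(0.6)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValidationError):
            node_score("u", "v", 1.2, 0.5, 0.5)


class TestAlign:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_self_alignment_identity(self, alpha):
        net = _net([("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        res = align(net, net, alpha=alpha)
        assert res.mapping == {n: n for n in net.graph.nodes()}
        assert res.ec == pytest.approx(100.0)
        assert res.ss == pytest.approx(100.0)

    def test_two_k2_graphs_conserve_edge(self):
        net1 = _net([("a", "b")])
        net2 = _net([("x", "y")])
        ident = pd.DataFrame(1.0, index=["a", "b", "x", "y"], columns=["a", "b", "x", "y"])
        res = align(net1, net2, alpha=0.5, seqsim=SeqSimilarityMatrix(ident))
        assert res.ec == pytest.approx(100.0)
        assert len(res.conserved_edges) == 1

    def test_deterministic(self, desk_data):
        from occnet.simulate import truth_networks

        n1, n2 = truth_networks(desk_data.truth)
        a = align(n1, n2, alpha=0.4, seqsim=desk_data.identity)
        b = align(n1, n2, alpha=0.4, seqsim=desk_data.identity)
        assert a.mapping == b.mapping and a.ec == b.ec

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            align(CooccurrenceNetwork(), _net([("a", "b")]), alpha=0.5)

    def test_variables_only_align_to_variables(self):
        net1 = _net([("a", "b")])
        net1.add_variable_node("pH")
        net1.add_edge("a", "pH", sign="copresence")
        net2 = _net([("a", "b")])
        net2.add_variable_node("pH")
        net2.add_edge("a", "pH", sign="copresence")
        res = align(net1, net2, alpha=0.5)
        assert res.mapping["pH"] == "pH"


class TestScores:
    def test_identity_self_alignment_100(self):
        net = _net([("a", "b"), ("b", "c")])
        ec, ss, cons = alignment_scores_from_mapping({n: n for n in "abc"}, net, net)
        assert ec == 100.0 and ss == 100.0 and len(cons) == 2

    def test_mapping_conserving_nothing(self):
        net1 = _net([("a", "b")], isolated=["c"])
        net2 = _net([("x", "y")], isolated=["z"])
        ec, ss, _ = alignment_scores_from_mapping({"a": "x", "b": "z"}, net1, net2)
        assert ec == 0.0 and ss == 0.0

    def test_formula_values(self):
        """|E1| = 4, edges induced on the image |E2'| = 6, conserved C = 2:
        EC = 100*2/4 = 50 and SS = 100*2/(4 + 6 - 2) = 25."""
        net1 = _net([("a", "b"), ("c", "d"), ("e", "f"), ("a", "c")])
        net2 = _net(
            [
                ("u1", "u2"),  # image of a-b: conserved
                ("u3", "u4"),  # image of c-d: conserved
                ("u1", "u4"),
                ("u2", "u3"),
                ("u2", "u5"),
                ("u4", "u6"),
            ]
        )
        mapping = {"a": "u1", "b": "u2", "c": "u3", "d": "u4", "e": "u5", "f": "u6"}
        ec, ss, conserved = alignment_scores_from_mapping(mapping, net1, net2)
        assert ec == pytest.approx(50.0)
        assert ss == pytest.approx(25.0)
        assert len(conserved) == 2

    def test_empty_source_edges_undefined(self):
        net1 = _net([], isolated=["a", "b"])
        net2 = _net([("x", "y")])
        ec, ss, _ = alignment_scores_from_mapping({"a": "x", "b": "y"}, net1, net2)
        assert ec is None and ss is None

    def test_relabeling_invariance(self, desk_data):
        from occnet.simulate import truth_networks
        import networkx as nx

        n1, n2 = truth_networks(desk_data.truth)
        res = align(n1, n2, alpha=0.0)
        relabel = {n: f"X{k}" for k, n in enumerate(sorted(n1.graph.nodes()))}
        relabel2 = {n: f"Y{k}" for k, n in enumerate(sorted(n2.graph.nodes()))}
        m1 = CooccurrenceNetwork(nx.relabel_nodes(n1.graph, relabel))
        m2 = CooccurrenceNetwork(nx.relabel_nodes(n2.graph, relabel2))
        mapped = {relabel[u]: relabel2[v] for u, v in res.mapping.items()}
        ec1, ss1, _ = alignment_scores_from_mapping(res.mapping, n1, n2)
        ec2, ss2, _ = alignment_scores_from_mapping(mapped, m1, m2)
        assert ec1 == pytest.approx(ec2)
        assert ss1 == pytest.approx(ss2)

    def test_adding_conserved_edge_never_decreases_ec(self):
        edges1 = [("a", "b"), ("b", "c")]
        edges2 = [("a", "b"), ("b", "c"), ("c", "d")]
        net1, net2 = _net(edges1, isolated=["d"]), _net(edges2)
        ident = {n: n for n in "abcd"}
        ec_before, _, _ = alignment_scores_from_mapping(ident, net1, net2)
        net1b = _net(edges1 + [("c", "d")])
        net2b = _net(edges2 + [("c", "d")])  # duplicate ignored by nx
        ec_after, _, _ = alignment_scores_from_mapping(ident, net1b, net2b)
        assert ec_after >= ec_before


class TestAlphaScan:
    def test_self_alignment_consensus_zero_by_tie_rule(self):
        net = _net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        table, consensus, results = alpha_scan(net, net)
        assert len(table) == 11
        assert np.allclose(table["EC"], 100.0)
        assert consensus == 0.0

    def test_grid_rows(self):
        net = _net([("a", "b"), ("b", "c")])
        table, _, _ = alpha_scan(net, net, grid=[0.0, 0.5, 1.0])
        assert list(table["alpha"]) == [0.0, 0.5, 1.0]

    def test_interior_consensus_on_informative_data(self):
        """When both topology and sequences are informative but imperfect
        (independently thinned edge sets), the consensus alpha is an interior
        grid point in most seeds."""
        import networkx as nx

        from occnet.simulate import desk_scale_config, simulate_dataset, truth_networks

        def thin(net, seed, frac=0.25):
            rng = np.random.default_rng(seed)
            g = net.graph.copy()
            edges = sorted(g.edges())
            drop = rng.choice(len(edges), size=int(frac * len(edges)), replace=False)
            g.remove_edges_from([edges[k] for k in drop])
            return CooccurrenceNetwork(g)

        interior = 0
        seeds = range(10, 17)
        for seed in seeds:
            data = simulate_dataset(desk_scale_config(seed))
            n1, n2 = truth_networks(data.truth)
            t1, t2 = thin(n1, seed * 2 + 1), thin(n2, seed * 2 + 2)
            _, consensus, _ = alpha_scan(
                t1, t2, seqsim=data.identity, grid=[0.0, 0.3, 0.6, 1.0]
            )
            interior += consensus not in (0.0, 1.0)
        assert interior >= 4


class TestCompareToRandom:
    def test_zero_randomizations_rejected(self):
        net = _net([("a", "b")])
        with pytest.raises(ValidationError):
            compare_to_random(net, net, n_random=0, alpha=0.5)

    def test_structured_pair_beats_random(self, desk_data):
        from occnet.simulate import truth_networks

        n1, n2 = truth_networks(desk_data.truth)
        cmp = compare_to_random(n1, n2, n_random=5, alpha=0.5,
                                seqsim=desk_data.identity, seed=0)
        assert cmp["z_ec"] > 2.0


class TestHiveplot:
    def test_export_structure(self, desk_data):
        from occnet.simulate import truth_networks

        n1, n2 = truth_networks(desk_data.truth)
        res = align(n1, n2, alpha=0.5, seqsim=desk_data.identity)
        rel = (desk_data.table.counts / desk_data.table.counts.sum(axis=0)).mean(axis=1)
        out = hiveplot_export(res, n1, n2, desk_data.truth.core_set, rel.to_dict())
        assert set(out["axes"]) == {"network1", "network2"}
        node = out["axes"]["network1"][0]
        assert {"id", "axis", "sub_axis", "log_abundance", "degree_centrality", "rank"} <= set(node)
        assert len(out["alignment_edges"]) == res.n_aligned
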