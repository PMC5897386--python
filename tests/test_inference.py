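"""Pair measures, candidate selection, edge testing, merging and network
statistics."""

import numpy as np
import pandas as pd
import pytest

from occnet.containers import CooccurrenceNetwork, OtuTable, ValidationError
from occnet.inference import (
    build_network,
    degree_distribution_verdict,
    merge_and_correct,
    network_stats,
    pair_score,
    randomize_network,
    reboot_edge_test,
    select_candidates,
)
from occnet.containers import EdgeTestResult

from conftest import random_otu_table


class TestPairScore:
    def test_identical_profiles(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pair_score(x, x, "bray_curtis") == pytest.approx(0.0)
        assert pair_score(x, x, "kullback_leibler") == pytest.approx(0.0)
        assert pair_score(x, x, "pearson") == pytest.approx(1.0)

    def test_disjoint_support_bray_curtis_one(self):
        x = np.array([1.0, 2.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 3.0, 1.0])
        assert pair_score(x, y, "bray_curtis") == pytest.approx(1.0)

    def test_proportional_profiles_correlate_perfectly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pair_score(x, 2 * x, "pearson") == pytest.approx(1.0)
        assert pair_score(x, 2 * x, "spearman") == pytest.approx(1.0)

    def test_constant_profile_rejected_for_correlations(self):
        with pytest.raises(ValidationError, match="constant"):
            pair_score([1, 1, 1, 1], [1, 2, 3, 4], "pearson")

    def test_symmetric_kl_nonnegative_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 30, size=8)
            y = rng.integers(0, 30, size=8)
            a = pair_score(x, y, "kullback_leibler")
            b = pair_score(y, x, "kullback_leibler")
            assert a >= 0 and a == pytest.approx(b)


def _table_from_counts(counts: np.ndarray, prefix="OTU") -> OtuTable:
    n_samples = counts.shape[1]
    n_sites = n_samples // 3
    samples = [f"S{s}R{r}" for s in range(1, n_sites + 1) for r in (1, 2, 3)]
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"{prefix}_{i}" for i in range(counts.shape[0])])
    meta = pd.DataFrame(
        {
            "site": [int(s.split("R")[0][1:]) for s in samples],
            "replicate": [int(s.split("R")[1]) for s in samples],
            "section": [1] * n_samples,
        },
        index=samples,
    )
    return OtuTable(df, pd.Series("k__B", index=df.index), meta)


class TestSelectCandidates:
    def test_toy_pair_topping_all_measures_selected(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 100, size=12)
        counts = np.vstack([
            base,
            base + rng.integers(0, 3, size=12),        # near-copy of OTU_0
            rng.integers(50, 100, size=12),            # unrelated
        ])
        t = _table_from_counts(counts)
        cands = select_candidates(t, n_pos=1, n_neg=0, minocc=10)
        assert any({c.u, c.v} == {"OTU_0", "OTU_1"} for c in cands)

    def test_pair_missing_from_one_measure_excluded(self):
        """A pair must appear in every applicable measure's selection; being
        top-ranked in only three of four is not enough."""
        rng = np.random.default_rng(2)
        n = 14
        counts = rng.integers(20, 120, size=(n, 12))
        t = _table_from_counts(counts)
        all_cands = select_candidates(t, n_pos=10**6, n_neg=10**6, minocc=10)
        few = select_candidates(t, n_pos=3, n_neg=0, minocc=10)
        few_pairs = {frozenset((c.u, c.v)) for c in few}
        # every restricted candidate must be within the top-3 of each measure;
        # verify by recomputing one measure's ranking
        from occnet.inference import make_context
        import scipy.stats as st

        ctx = make_context(t.subset_otus([o for o in t.otu_ids]))
        pear = np.corrcoef(ctx.rel)
        iu, ju = np.triu_indices(n, 1)
        order = np.argsort(-pear[iu, ju])[:3]
        top3 = {frozenset((t.otu_ids[iu[k]], t.otu_ids[ju[k]])) for k in order}
        assert few_pairs <= top3
        assert few_pairs <= {frozenset((c.u, c.v)) for c in all_cands}

    def test_threshold_free_limit_gives_sign_agreement_pairs(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(20, 120, size=(8, 12))
        t = _table_from_counts(counts)
        with pytest.warns(UserWarning):
            cands = select_candidates(t, n_pos=10**6, n_neg=10**6, minocc=10)
        for c in cands:
            pr, sr = c.observed["pearson"], c.observed["spearman"]
            if c.sign == "copresence":
                assert pr > 0 and sr > 0
            else:
                assert pr < 0 and sr < 0

    def test_row_and_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        t = random_otu_table(rng, n_otus=15)
        t.counts += 5  # comfortable occurrence
        c1 = {
            frozenset((c.u, c.v))
            for c in select_candidates(t, n_pos=20, n_neg=20, minocc=5)
        }
        perm = list(rng.permutation(t.otu_ids))
        t2 = OtuTable(t.counts.loc[perm], t.taxonomy.loc[perm], t.sample_meta)
        c2 = {
            frozenset((c.u, c.v))
            for c in select_candidates(t2, n_pos=20, n_neg=20, minocc=5)
        }
        assert c1 == c2


class TestRebootEdgeTest:
    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.integers(10, 200, size=12)
        y = rng.integers(10, 200, size=12)
        a = reboot_edge_test(x, y, "pearson", n=100, seed=7)
        b = reboot_edge_test(x, y, "pearson", n=100, seed=7)
        assert a == b

    def test_duplicated_profile_strongly_significant(self):
        """A profile tested against its own copy inside a rich table context
        yields p < 0.001 for Pearson."""
        rng = np.random.default_rng(6)
        base = np.exp(rng.normal(0, 1, size=(40, 12)))
        props = base / base.sum(axis=0)
        depths = rng.integers(5000, 20000, size=12)
        counts = np.vstack([rng.multinomial(d, props[:, s]) for s, d in enumerate(depths)]).T
        x = counts[0] * 2 + rng.integers(0, 3, size=12)
        totals = counts.sum(axis=0) + x
        res = reboot_edge_test(counts[0], x, "pearson", n=1000, seed=8, totals=totals)
        assert res.p_value < 0.001

    def test_null_pair_rarely_significant(self):
        rng = np.random.default_rng(7)
        rejected = 0
        base = np.exp(rng.normal(0, 1.5, size=30))
        props = base / base.sum()
        depths = rng.integers(3900, 26001, size=12)
        counts = np.vstack([rng.multinomial(d, props) for d in depths]).T
        totals = counts.sum(axis=0)
        for k in range(60):
            i, j = rng.choice(30, size=2, replace=False)
            res = reboot_edge_test(counts[i], counts[j], "pearson", n=200,
                                   seed=int(rng.integers(2**31 - 1)), totals=totals)
            rejected += res.p_value < 0.05
        assert rejected <= 10


class TestMergeAndCorrect:
    def _tests(self, pmap):
        return {
            ms: EdgeTestResult(ms, 0.5, 0.0, 0.1, p, -1, 1, killed=False)
            for ms, p in pmap.items()
        }

    def test_single_measure_passthrough(self):
        out = merge_and_correct([self._tests({"pearson": 0.01})])
        assert out["p_merged"].iloc[0] == pytest.approx(0.01)

    def test_all_ones_dropped(self):
        out = merge_and_correct([self._tests({"pearson": 1.0, "spearman": 1.0})])
        assert out["q"].iloc[0] == pytest.approx(1.0)
        assert not out["keep"].iloc[0]

    def test_four_independent_005_fisher_significant(self):
        """-2 * sum(ln 0.05) = 23.97 on 8 df: the merged p is ~0.0023."""
        out = merge_and_correct(
            [self._tests({m: 0.05 for m in ("pearson", "spearman", "bray_curtis", "kullback_leibler")})]
        )
        assert out["p_merged"].iloc[0] == pytest.approx(0.00226, rel=0.05)
        assert out["keep"].iloc[0]

    def test_killed_measures_excluded(self):
        tests = self._tests({"pearson": 0.001, "spearman": 0.9})
        tests["pearson"].killed = True
        out = merge_and_correct([tests])
        assert out["p_merged"].iloc[0] == pytest.approx(0.9)


class TestNetworkStats:
    def _net(self, edges):
        net = CooccurrenceNetwork()
        nodes = {n for e in edges for n in e}
        for n in sorted(nodes):
            net.add_otu_node(n)
        for u, v in edges:
            net.add_edge(u, v, sign="copresence")
        return net

    def test_triangle(self):
        s = network_stats(self._net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert s.clustering_coefficient == pytest.approx(1.0)
        assert s.density == pytest.approx(1.0)
        assert s.heterogeneity == pytest.approx(0.0)
        assert s.characteristic_path_length == pytest.approx(1.0)

    def test_path_of_three(self):
        s = network_stats(self._net([("a", "b"), ("b", "c")]))
        assert s.clustering_coefficient == pytest.approx(0.0)
        assert s.density == pytest.approx(2 / 3)
        # pairs: a-b 1, b-c 1, a-c 2 -> mean 4/3
        assert s.characteristic_path_length == pytest.approx(4 / 3)

    def test_k_regular_heterogeneity_zero(self):
        import networkx as nx

        g = nx.cycle_graph(8)
        net = CooccurrenceNetwork()
        for n in g.nodes():
            net.add_otu_node(str(n))
        for u, v in g.edges():
            net.add_edge(str(u), str(v), sign="copresence")
        assert network_stats(net).heterogeneity == pytest.approx(0.0)


class TestDegreeVerdict:
    def test_small_graph_inconclusive(self):
        assert degree_distribution_verdict(list(range(1, 11))) == "inconclusive"

    def test_poisson_degrees_look_erdos_renyi(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(10):
            d = rng.poisson(5, size=500)
            hits += degree_distribution_verdict(d) == "erdos-renyi-like"
        assert hits >= 9

    def test_zipf_degrees_look_power_law(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            d = rng.zipf(2.5, size=500)
            hits += degree_distribution_verdict(d) == "power-law-like"
        assert hits >= 9


class TestRandomize:
    def test_zero_edges_unchanged(self):
        net = CooccurrenceNetwork()
        for n in "abcd":
            net.add_otu_node(n)
        out = randomize_network(net, seed=1)
        assert out.n_edges == 0 and set(out.graph.nodes()) == set("abcd")

    def test_conservation_of_nodes_and_edges(self, desk_data):
        from occnet.simulate import truth_networks

        net, _ = truth_networks(desk_data.truth)
        for seed in range(5):
            rnd = randomize_network(net, seed=seed)
            assert set(rnd.graph.nodes()) == set(net.graph.nodes())
            assert rnd.n_edges == net.n_edges
            assert not any(u == v for u, v in rnd.graph.edges())

    def test_degree_sequence_decorrelates_with_repeats(self, desk_data):
        from occnet.simulate import truth_networks

        net, _ = truth_networks(desk_data.truth)
        nodes = sorted(net.graph.nodes())
        orig = np.array([net.graph.degree(n) for n in nodes])
        once = randomize_network(net, seed=3)
        d1 = np.array([once.graph.degree(n) for n in nodes])
        many = once
        for k in range(4):
            many = randomize_network(many, seed=10 + k)
        d4 = np.array([many.graph.degree(n) for n in nodes])
        c1 = np.corrcoef(orig, d1)[0, 1]
        c4 = np.corrcoef(orig, d4)[0, 1]
        assert c1 < 1.0
        assert c4 < c1


class TestBuildNetwork:
    def test_variable_nodes_bounded_by_configuration(self, desk_data):
        from occnet.profiles import filter_min_samples, filter_replicate_consistency

        tab = filter_replicate_consistency(desk_data.table)
        s1 = filter_min_samples(tab.section_slice(1), 5)
        net = build_network(
            s1, desk_data.gradient, n_perm=100, seed=42,
            variables=("pH", "Fe"),
        )
        assert set(net.variable_nodes) <= {"pH", "Fe"}

    def test_permuted_labels_destroy_most_edges(self, desk_data):
        """Shuffling each OTU's counts across samples independently destroys
        the planted associations; the inferred network shrinks to a small
        fraction of the structured run's edge count."""
        from occnet.profiles import filter_min_samples, filter_replicate_consistency

        tab = filter_replicate_consistency(desk_data.table)
        s1 = filter_min_samples(tab.section_slice(1), 5)
        structured = build_network(s1, desk_data.gradient, n_perm=100, seed=42)

        rng = np.random.default_rng(0)
        shuffled = s1.counts.to_numpy().copy()
        for i in range(shuffled.shape[0]):
            rng.shuffle(shuffled[i])
        t2 = OtuTable(
            pd.DataFrame(shuffled, index=s1.counts.index, columns=s1.counts.columns),
            s1.taxonomy,
            s1.sample_meta,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_net = build_network(t2, None, n_perm=100, seed=42)
        assert null_net.n_edges <= 0.05 * max(structured.n_edges, 1)

    def test_copresence_edges_have_positive_correlations(self, desk_data):
        from occnet.profiles import filter_min_samples, filter_replicate_consistency

        tab = filter_replicate_consistency(desk_data.table)
        s1 = filter_min_samples(tab.section_slice(1), 5)
        net = build_network(s1, desk_data.gradient, n_perm=100, seed=7)
        for u, v, data in net.graph.edges(data=True):
            scores = data["scores"]
            if data["sign"] == "copresence":
                assert scores["pearson"] > 0 and scores["spearman"] > 0
            else:
                assert scores["pearson"] < 0 and scores["spearman"] < 0
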