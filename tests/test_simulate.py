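"""Properties of the synthetic-community generator and its planted truth."""

import numpy as np
import pytest
from scipy import stats

from occnet.containers import ValidationError
from occnet.simulate import (
    SimulationConfig,
    desk_scale_config,
    generate_community,
    generate_gradient,
    plant_functions,
    simulate_dataset,
    truth_networks,
)


class TestConfig:
    def test_infeasible_core_plus_swaps_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            SimulationConfig(seed=1, n_otus=100, n_core=90, n_roleswap_pairs=10)

    def test_depth_below_rarefaction_rejected(self):
        with pytest.raises(ValidationError, match="depth"):
            SimulationConfig(seed=1, depth_range=(1000, 5000))

    def test_too_many_factors_for_section_rejected(self):
        with pytest.raises(ValidationError, match="factor"):
            SimulationConfig(seed=1, n_latent_factors=12)


class TestGradient:
    def test_ph_endpoints_and_monotonicity(self):
        cfg = SimulationConfig(seed=5)
        grad = generate_gradient(cfg)
        ph = grad.values.loc["pH"]
        site_means = [
            ph[[f"S{s}R{r}" for r in (1, 2, 3)]].mean() for s in range(1, 9)
        ]
        assert site_means[0] == pytest.approx(8.8, abs=0.3)
        assert site_means[-1] == pytest.approx(5.7, abs=0.3)

    def test_zero_noise_trends_strictly_monotone(self):
        cfg = SimulationConfig(seed=5, gradient_noise=0.0)
        grad = generate_gradient(cfg)
        ph = grad.values.loc["pH", [f"S{s}R1" for s in range(1, 9)]].to_numpy()
        assert np.all(np.diff(ph) < 0)
        rh = grad.values.loc["RelativeHumidity", [f"S{s}R1" for s in range(1, 9)]].to_numpy()
        assert np.all(np.diff(rh) > 0)
        fe = grad.values.loc["Fe", [f"S{s}R1" for s in range(1, 9)]].to_numpy()
        assert np.all(np.diff(fe) > 0)
        k = grad.values.loc["K", [f"S{s}R1" for s in range(1, 9)]].to_numpy()
        assert np.all(np.diff(k) < 0)

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=6)
        a = generate_gradient(cfg)
        b = generate_gradient(cfg)
        assert a.values.equals(b.values)


class TestCommunity:
    def test_top50_abundance_concentration_band(self):
        data = simulate_dataset(SimulationConfig(seed=3))
        rel = data.table.counts / data.table.counts.sum(axis=0)
        for s in data.table.sample_ids:
            share = rel[s].sort_values(ascending=False).iloc[:50].sum()
            assert 0.50 <= share <= 0.75

    def test_deterministic_outputs(self):
        a = simulate_dataset(desk_scale_config(9))
        b = simulate_dataset(desk_scale_config(9))
        assert a.table.counts.equals(b.table.counts)
        assert a.identity.identity.equals(b.identity.identity)
        assert a.truth.to_json_dict() == b.truth.to_json_dict()

    def test_noiseless_limit_matches_model_proportions(self):
        cfg = desk_scale_config(4, noise_dispersion=0.0, depth_range=(500_000, 500_000))
        data = simulate_dataset(cfg)
        rel = (data.table.counts / data.table.counts.sum(axis=0)).to_numpy()
        model = data.truth.model_proportions.to_numpy()
        assert np.abs(rel - model).max() < 5e-3

    def test_planted_positive_pair_spearman(self):
        """OTUs sharing a factor with same-sign loadings co-occur: their
        abundance profiles correlate positively in nearly every run."""
        hits = trials = 0
        for seed in range(100):
            data = simulate_dataset(desk_scale_config(seed))
            L = data.truth.loadings
            # first two same-sign members of the largest factor group
            col = L.abs().sum(axis=0).idxmax()
            members = L.index[(L[col] > 0)][:2]
            s1 = data.table.samples_in_section(1)
            x = data.table.counts.loc[members[0], s1]
            y = data.table.counts.loc[members[1], s1]
            rho = stats.spearmanr(x, y)[0]
            trials += 1
            hits += rho > 0
        assert hits / trials >= 0.95

    def test_sequence_identity_bands(self, desk_data):
        ident = desk_data.identity.identity
        assert np.allclose(np.diag(ident), 1.0)
        tax = desk_data.table.taxonomy
        otus = list(ident.index)[:40]
        for i, a in enumerate(otus):
            for b in otus[i + 1 :]:
                v = ident.at[a, b]
                pa = tax[a].split("p__")[1].split(";")[0]
                pb = tax[b].split("p__")[1].split(";")[0]
                ga = tax[a].split("g__")[1]
                gb = tax[b].split("g__")[1]
                if ga == gb:
                    assert 0.97 <= v <= 0.995
                elif pa == pb:
                    assert 0.85 <= v <= 0.93
                else:
                    assert 0.75 <= v <= 0.83


class TestTruth:
    def test_roleswap_disjoint_from_core(self, desk_data):
        truth = desk_data.truth
        swaps = set(truth.roleswap_map) | set(truth.roleswap_map.values())
        assert not (swaps & truth.core_set)

    def test_true_edges_join_section_copresent_nodes(self, desk_data):
        truth = desk_data.truth
        s2_only = set(truth.roleswap_map.values())
        s1_only = set(truth.roleswap_map)
        for a, b, _ in truth.true_edges[1]:
            assert not ({a, b} & s2_only)
        for a, b, _ in truth.true_edges[2]:
            assert not ({a, b} & s1_only)

    def test_planted_edges_pass_occurrence_filters(self, desk_data):
        """Every strong planted edge joins OTUs occurring in >= 10 of their
        section's samples, so edges are discoverable after filtering."""
        table, truth = desk_data.table, desk_data.truth
        for section in (1, 2):
            samples = table.samples_in_section(section)
            occ = (table.counts[samples] > 0).sum(axis=1)
            otus = {
                n
                for a, b, _ in truth.true_edges[section]
                for n in (a, b)
                if n in table.counts.index
            }
            assert all(occ[o] >= 10 for o in otus)

    def test_structural_networks_contain_strong_tier(self, desk_data):
        strong1, strong2 = truth_networks(desk_data.truth, tier="strong")
        full1, full2 = truth_networks(desk_data.truth, tier="structural")
        assert strong1.edges_as_set() <= full1.edges_as_set()
        assert strong2.edges_as_set() <= full2.edges_as_set()

    def test_section_symmetry_of_design(self, desk_data):
        """Role-swap partners have identical loading rows, so the two
        sections' planted OTU-OTU structures are exchangeable."""
        truth = desk_data.truth
        L = truth.loadings
        for a, b in truth.roleswap_map.items():
            assert np.allclose(L.loc[a], L.loc[b])
        relabel = dict(truth.roleswap_map)
        e1 = {
            frozenset((relabel.get(a, a), relabel.get(b, b)))
            for a, b, _ in truth.true_edges[1]
        }
        e2 = {frozenset((a, b)) for a, b, _ in truth.true_edges[2]}
        assert e1 == e2


class TestFunctions:
    def test_core_label_fraction_enriched(self, desk_data):
        truth = desk_data.truth
        labels = truth.function_labels
        core = truth.core_set
        noncore = set(truth.roleswap_map) | set(truth.roleswap_map.values())
        f_core = np.mean([
            "nitrogen_fixation" in labels.get(o, []) for o in core
        ])
        f_non = np.mean([
            "nitrogen_fixation" in labels.get(o, []) for o in noncore
        ])
        assert f_core > f_non

    def test_enrichment_one_removes_difference(self):
        data = simulate_dataset(desk_scale_config(2, nfix_enrichment=1.0))
        labels = data.truth.function_labels
        core = data.truth.core_set
        noncore = set(data.truth.roleswap_map) | set(data.truth.roleswap_map.values())
        f_core = np.mean(["nitrogen_fixation" in labels.get(o, []) for o in core])
        f_non = np.mean(["nitrogen_fixation" in labels.get(o, []) for o in noncore])
        assert abs(f_core - f_non) < 0.1

    def test_community_share_between_core_and_noncore(self, desk_data):
        """Within-set nitrogen-fixation shares mix: the whole community's
        value lies between the enriched core and the depleted rest."""
        from occnet.corefunc import function_profile

        truth, tab = desk_data.truth, desk_data.table
        labels = {k: set(v) for k, v in truth.function_labels.items()}
        rest = sorted(set(tab.otu_ids) - truth.core_set)
        kwargs = dict(normalize="set", categories=["nitrogen_fixation"])
        core_m = function_profile(
            truth.core_set, tab, labels, range(1, 9), **kwargs
        ).mean["nitrogen_fixation"]
        rest_m = function_profile(rest, tab, labels, range(1, 9), **kwargs).mean[
            "nitrogen_fixation"
        ]
        all_m = function_profile(tab.otu_ids, tab, labels, range(1, 9), **kwargs).mean[
            "nitrogen_fixation"
        ]
        assert rest_m <= all_m <= core_m

    def test_plant_functions_returns_bundle_and_labels(self, desk_data):
        rules, labels = plant_functions(
            desk_data.truth, desk_data.table.taxonomy, desk_data.config
        )
        assert len(rules) >= 15
        assert labels == desk_data.truth.function_labels
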