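import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import microtempo as mt
from microtempo.io import CountTable
from microtempo.network import _nearest_rank_threshold, network_from_edges


def _brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    nodes = list(graph.nodes)
    bt = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(v in p for p in paths)
            bt[v] += on / len(paths)
    return bt


class TestPrevalenceFilter:
    def _table(self):
        counts = pd.DataFrame(
            np.zeros((3, 100), dtype=int),
            index=["rare19", "edge20", "common"],
            columns=[f"s{i}" for i in range(100)],
        )
        counts.loc["rare19", counts.columns[:19]] = 1
        counts.loc["edge20", counts.columns[:20]] = 1
        counts.loc["common"] = 1
        return CountTable(counts)

    def test_below_threshold_removed_boundary_retained(self):
        out = mt.prevalence_filter(self._table(), 0.20)
        assert "rare19" not in out.asv_ids
        assert "edge20" in out.asv_ids and "common" in out.asv_ids

    def test_zero_threshold_is_identity(self):
        table = self._table()
        out = mt.prevalence_filter(table, 0.0)
        assert out.asv_ids == table.asv_ids

    def test_everything_removed_rejected(self):
        counts = pd.DataFrame(
            np.zeros((2, 10), dtype=int),
            index=["a", "b"], columns=[f"s{i}" for i in range(10)],
        )
        counts.iloc[:, 0] = 1  # both ASVs at 10% prevalence
        with pytest.raises(ValueError):
            mt.prevalence_filter(CountTable(counts), 0.5)


class TestCentrality:
    def test_star_graph_hand_counts(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        net = network_from_edges(edges)
        assert net.nodes.loc["hub", "degree"] == 5
        assert net.nodes.loc["hub", "betweenness"] == pytest.approx(10.0)  # C(5,2)
        for i in range(5):
            assert net.nodes.loc[f"leaf{i}", "degree"] == 1
            assert net.nodes.loc[f"leaf{i}", "betweenness"] == 0.0

    def test_betweenness_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(6):
            n = int(rng.integers(5, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(10000)))
            expect = _brute_force_betweenness(g)
            got = nx.betweenness_centrality(g, normalized=False)
            for v in g.nodes:
                assert got[v] == pytest.approx(expect[v], abs=1e-9)


class TestEstimateNetwork:
    def _planted_pair(self, seed=0):
        edges = tuple((i, i + 1) for i in range(29))
        cfg = mt.SynthConfig(
            n_asvs=30, seed=seed, network_edges=edges,
            seasonal_frac=0.0, season_amplitude=0.0, drift_frac=0.0,
            interaction_sd=0.0, genotype_sd=0.0, noise_sd=1.0, base_sd=1.0,
            reps_min=3, reps_max=3,
        )
        table, meta, _, truth = mt.generate_dataset(cfg)
        bact = CountTable(table.counts.iloc[:15], "rhizosphere", "bacteria_archaea")
        fung = CountTable(table.counts.iloc[15:], "rhizosphere", "fungi")
        return bact, fung, truth

    def test_chain_recovery_single_seed(self):
        bact, fung, truth = self._planted_pair(seed=1)
        net = mt.estimate_network(bact, fung, mt.NetworkConfig(seed=1))
        est = {frozenset(e) for e in net.graph.edges}
        tru = {frozenset(e) for e in truth.edges}
        tp = len(est & tru)
        f1 = 2 * tp / (len(est) + len(tru))
        assert f1 >= 0.7
        assert not any(a == b for a, b in net.graph.edges)  # no self loops

    def test_stars_instability_bounded_and_small_at_lambda_max(self):
        bact, fung, _ = self._planted_pair(seed=2)
        net = mt.estimate_network(bact, fung, mt.NetworkConfig(seed=2))
        assert (net.instability <= 0.5 + 1e-12).all()
        assert net.instability[0] <= 0.05  # near-empty graph at lambda_max

    def test_or_rule_superset_of_and_rule_at_fixed_penalty(self):
        from microtempo.network import _neighborhoods, _symmetrize
        from microtempo.normalize import clr_transform

        bact, fung, _ = self._planted_pair(seed=3)
        X = pd.concat([clr_transform(bact), clr_transform(fung)]).to_numpy().T
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        for lam in (0.3, 0.15, 0.05):
            sel = _neighborhoods(X, np.array([lam]))[0]
            adj_or = _symmetrize(sel, "OR")
            adj_and = _symmetrize(sel, "AND")
            assert not (adj_and & ~adj_or).any()

    def test_independent_nodes_stay_sparse(self):
        cfg = mt.SynthConfig(
            n_asvs=30, seed=4, seasonal_frac=0.0, season_amplitude=0.0,
            drift_frac=0.0, interaction_sd=0.0, genotype_sd=0.0, noise_sd=1.0,
            base_sd=1.0, reps_min=3, reps_max=3,
        )
        table, *_ = mt.generate_dataset(cfg)
        bact = CountTable(table.counts.iloc[:15], "rhizosphere", "bacteria_archaea")
        fung = CountTable(table.counts.iloc[15:], "rhizosphere", "fungi")
        net = mt.estimate_network(bact, fung, mt.NetworkConfig(seed=4))
        possible = 30 * 29 / 2
        assert len(net.edges) <= 0.05 * possible

    def test_too_few_shared_samples_rejected(self):
        counts = pd.DataFrame(
            np.random.default_rng(0).integers(1, 5, (4, 5)),
            index=list("abcd"), columns=[f"s{i}" for i in range(5)],
        )
        t = CountTable(counts, "rhizosphere", "bacteria_archaea")
        f = CountTable(counts.rename(index=str.upper), "rhizosphere", "fungi")
        with pytest.raises(ValueError, match="shared"):
            mt.estimate_network(t, f, mt.NetworkConfig())


class TestHubs:
    def _star_net_and_table(self, center_abundant=True):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        net = network_from_edges(edges)
        counts = pd.DataFrame(
            {"s1": [1000 if center_abundant else 1] + [200] * 5,
             "s2": [1000 if center_abundant else 1] + [200] * 5},
            index=["hub"] + [f"leaf{i}" for i in range(5)],
        )
        return net, CountTable(counts)

    def test_star_center_is_hub_leaves_are_not(self):
        net, table = self._star_net_and_table()
        hubs = mt.identify_hubs(net, table, core=["hub"] + [f"leaf{i}" for i in range(5)])
        assert list(hubs.index) == ["hub"]

    def test_abundance_filter_excludes_center(self):
        net, table = self._star_net_and_table(center_abundant=False)
        hubs = mt.identify_hubs(net, table, core=["hub"])
        assert len(hubs) == 0

    def test_core_filter_excludes_center(self):
        net, table = self._star_net_and_table()
        hubs = mt.identify_hubs(net, table, core=[f"leaf{i}" for i in range(5)])
        assert len(hubs) == 0

    def test_identical_centralities_all_pass_percentile(self):
        g = nx.cycle_graph(6)  # every node degree 2, equal betweenness
        net = network_from_edges(list(g.edges), nodes=list(g.nodes))
        counts = pd.DataFrame(
            {"s1": [10] * 6, "s2": [10] * 6}, index=[str(v) for v in g.nodes]
        )
        net.nodes.index = [str(v) for v in net.nodes.index]
        hubs = mt.identify_hubs(
            net, CountTable(counts), core=[str(v) for v in g.nodes]
        )
        assert len(hubs) == 6

    def test_nearest_rank_percentile_inclusive(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        assert _nearest_rank_threshold(values, 0.90) == 9.0

    def test_empty_network_rejected(self):
        net = network_from_edges([])
        counts = pd.DataFrame({"s1": [1], "s2": [1]}, index=["a"])
        with pytest.raises(ValueError):
            mt.identify_hubs(net, CountTable(counts), core=["a"])
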