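import itertools

import networkx as nx
import numpy as np
import pytest

from weaklink.metrics import (
    Partition,
    betweenness,
    degree_strength,
    hub_ranking,
    louvain_partition,
    modularity_q,
    shortest_paths,
    to_distance,
)
from weaklink.network import WeightedNetwork

from conftest import random_network


def net_from_edges(edges, n=None):
    nodes = sorted({v for e in edges for v in e[:2]})
    if n is not None:
        nodes = [f"n{i}" for i in range(n)]
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, wt in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = wt
    return WeightedNetwork(nodes=tuple(str(v) for v in nodes), weights=w)


# ---------------------------------------------------------------- oracles


def brute_force_paths(net):
    """Exhaustive simple-path enumeration: min-sum lengths and counts."""
    d = to_distance(net)
    n = net.n_nodes
    lengths = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    np.fill_diagonal(lengths, 0.0)
    np.fill_diagonal(counts, 1.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best, cnt = np.inf, 0
            for k in range(n - 1):
                for mid in itertools.permutations(
                    [v for v in range(n) if v not in (s, t)], k
                ):
                    path = (s, *mid, t)
                    if any(d[a, b] == np.inf for a, b in zip(path, path[1:])):
                        continue
                    length = sum(d[a, b] for a, b in zip(path, path[1:]))
                    if length < best - 1e-10:
                        best, cnt = length, 1
                    elif length <= best + 1e-10:
                        cnt += 1
            lengths[s, t], counts[s, t] = best, cnt
    return lengths, counts


def brute_force_betweenness(net):
    lengths, counts = brute_force_paths(net)
    n = net.n_nodes
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if counts[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if lengths[s, v] + lengths[v, t] <= lengths[s, t] + 1e-10:
                    b[v] += counts[s, v] * counts[v, t] / counts[s, t]
    return b


def all_partitions(n):
    """Every set partition of range(n) as a label vector."""
    if n == 0:
        yield []
        return
    for labels in itertools.product(*[range(i + 1) for i in range(n)]):
        # restricted-growth check makes each partition appear exactly once
        if all(labels[i] <= max(labels[:i], default=-1) + 1 for i in range(n)):
            yield list(labels)


# ----------------------------------------------------------------- tests


class TestDegreeStrength:
    def test_triangle_hand_sums(self):
        net = net_from_edges([("a", "b", 0.2), ("a", "c", 0.3), ("b", "c", 0.4)])
        t = degree_strength(net)
        assert t.loc["a", "strength"] == pytest.approx(0.5)
        assert t.loc["b", "strength"] == pytest.approx(0.6)
        assert t.loc["c", "strength"] == pytest.approx(0.7)
        assert (t["degree"] == 2).all()

    def test_empty_network(self):
        net = WeightedNetwork(nodes=("a", "b"), weights=np.zeros((2, 2)))
        t = degree_strength(net)
        assert (t == 0).all().all()

    def test_handshake_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_network(8, 0.5, rng)
            t = degree_strength(net)
            assert t["degree"].sum() == 2 * net.n_links


class TestDistance:
    def test_weak_link_distance(self):
        net = net_from_edges([("a", "b", 0.12)])
        d = to_distance(net)
        assert d[0, 1] == pytest.approx(0.88)

    def test_absent_link_infinite(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.5)])
        assert to_distance(net)[0, 2] == np.inf

    def test_weight_one_rejected_citing_edge(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
        net = WeightedNetwork(nodes=("a", "b"), weights=w)
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            to_distance(net)


class TestShortestPaths:
    def test_chain(self):
        net = net_from_edges([("a", "b", 0.6), ("b", "c", 0.6)])  # D = 0.4 each
        lengths, counts = shortest_paths(to_distance(net))
        assert lengths[0, 2] == pytest.approx(0.8)
        assert counts[0, 2] == 1

    def test_complete_uniform_graph_uses_direct_links(self):
        n = 5
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0)
        net = WeightedNetwork(nodes=tuple(f"n{i}" for i in range(n)), weights=w)
        lengths, counts = shortest_paths(to_distance(net))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(lengths[off], 0.5)
        assert np.allclose(counts[off], 1)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            net = random_network(5, 0.6, rng)
            lengths, counts = shortest_paths(to_distance(net))
            bl, bc = brute_force_paths(net)
            assert np.allclose(lengths, bl, atol=1e-9)
            assert np.allclose(counts, bc)


class TestBetweenness:
    def test_chain_middle_node(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.5)])
        b = betweenness(net)
        assert b["b"] == pytest.approx(1.0)
        assert b["a"] == b["c"] == 0.0

    def test_star_center(self):
        net = net_from_edges([("hub", f"leaf{i}", 0.5) for i in range(5)])
        b = betweenness(net)
        assert b["hub"] == pytest.approx(10.0)  # C(5, 2)

    def test_complete_uniform_graph_all_zero(self):
        n = 6
        w = np.full((n, n), 0.4)
        np.fill_diagonal(w, 0)
        net = WeightedNetwork(nodes=tuple(f"n{i}" for i in range(n)), weights=w)
        assert (betweenness(net) == 0).all()

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            net = random_network(6, 0.5, rng)
            b = betweenness(net).to_numpy()
            assert np.allclose(b, brute_force_betweenness(net), atol=1e-9)
            g = nx.from_numpy_array(to_distance_finite(net))
            nxb = nx.betweenness_centrality(g, weight="weight", normalized=False)
            assert np.allclose(b, [nxb[i] for i in range(net.n_nodes)], atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        net = random_network(7, 0.5, rng)
        b = betweenness(net)
        perm = rng.permutation(7)
        net_p = WeightedNetwork(
            nodes=tuple(net.nodes[i] for i in perm),
            weights=net.weights[np.ix_(perm, perm)],
        )
        b_p = betweenness(net_p)
        for name in net.nodes:
            assert b_p[name] == pytest.approx(b[name], abs=1e-12)


def to_distance_finite(net):
    d = to_distance(net)
    d[~np.isfinite(d)] = 0.0  # networkx: absent edge = no entry
    return d


class TestModularity:
    def test_two_disconnected_cliques(self):
        edges = [(a, b, 0.5) for a, b in itertools.combinations("abcd", 2)]
        edges += [(a, b, 0.5) for a, b in itertools.combinations("efgh", 2)]
        net = net_from_edges(edges)
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        assert modularity_q(net, labels) == pytest.approx(0.5)

    def test_singleton_partition_negative(self):
        rng = np.random.default_rng(4)
        net = random_network(6, 0.6, rng)
        assert modularity_q(net, list(range(6))) < 0

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(5)
        net = random_network(6, 0.6, rng)
        assert modularity_q(net, [0] * 6) == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance_and_networkx_agreement(self):
        rng = np.random.default_rng(6)
        net = random_network(7, 0.5, rng)
        labels = [0, 1, 0, 2, 1, 2, 0]
        relabeled = [{0: 5, 1: 9, 2: 7}[c] for c in labels]
        q = modularity_q(net, labels)
        assert modularity_q(net, relabeled) == pytest.approx(q, abs=1e-12)
        g = nx.from_numpy_array(net.weights)
        coms = [{i for i in range(7) if labels[i] == c} for c in (0, 1, 2)]
        assert q == pytest.approx(
            nx.community.modularity(g, coms, weight="weight"), abs=1e-12
        )

    def test_partial_assignment_rejected(self):
        net = net_from_edges([("a", "b", 0.5)])
        with pytest.raises(ValueError):
            modularity_q(net, {"a": 0})


class TestLouvain:
    def test_two_cliques_weak_bridge(self):
        edges = [(a, b, 0.6) for a, b in itertools.combinations("abcd", 2)]
        edges += [(a, b, 0.6) for a, b in itertools.combinations("efgh", 2)]
        edges += [("d", "e", 0.05)]
        net = net_from_edges(edges)
        part = louvain_partition(net, seed=0, n_restarts=20)
        labels = dict(zip(net.nodes, part.labels))
        assert len({labels[c] for c in "abcd"}) == 1
        assert len({labels[c] for c in "efgh"}) == 1
        assert labels["a"] != labels["e"]

    def test_hundred_repetitions_identical(self, planted_net):
        net, _ = planted_net
        parts = [louvain_partition(net, seed=42, n_restarts=10) for _ in range(100)]
        assert all(p.labels == parts[0].labels for p in parts)
        assert all(p.q == parts[0].q for p in parts)

    def test_matches_exhaustive_maximum_on_small_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(4):
            net = random_network(6, 0.5, rng)
            part = louvain_partition(net, seed=1, n_restarts=50)
            best = max(
                modularity_q(net, labels) for labels in all_partitions(6)
            )
            assert part.q == pytest.approx(best, abs=1e-9)

    def test_empty_network_singletons(self):
        net = WeightedNetwork(nodes=("a", "b", "c"), weights=np.zeros((3, 3)))
        part = louvain_partition(net, seed=0)
        assert part.q == 0.0
        assert len(set(part.labels)) == 3

    def test_never_below_trivial_partitions(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            net = random_network(8, 0.4, rng)
            part = louvain_partition(net, seed=2, n_restarts=10)
            assert part.q >= modularity_q(net, [0] * 8) - 1e-12
            assert part.q >= modularity_q(net, list(range(8))) - 1e-12


class TestHubRanking:
    def test_dominant_node_is_rank_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {"strength": [5.0, 1.0, 1.0, 1.0], "betweenness": [3.0, 0, 0, 0]},
            index=["big", "a", "b", "c"],
        )
        rep = hub_ranking({"Task": df})
        assert rep["conditions"]["Task"]["strength"]["ranking"][0] == "big"
        assert "big" in rep["conditions"]["Task"]["strength"]["hubs"]

    def test_identical_tables_empty_change_summary(self):
        import pandas as pd

        df = pd.DataFrame(
            {"strength": [2.0, 1.0], "betweenness": [1.0, 0.0]}, index=["a", "b"]
        )
        rep = hub_ranking({"Task": df, "Task+AgonistStim": df.copy()})
        assert rep["changes"]["strength"] == []
        assert rep["changes"]["betweenness"] == []

    def test_differing_hubs_reported(self):
        import pandas as pd

        d1 = pd.DataFrame({"strength": [3.0, 1.0, 0.5],
                           "betweenness": [1.0, 0.5, 0.0]}, index=["a", "b", "c"])
        d2 = pd.DataFrame({"strength": [0.5, 1.0, 3.0],
                           "betweenness": [0.0, 0.5, 1.0]}, index=["a", "b", "c"])
        rep = hub_ranking({"Task": d1, "Task+AgonistStim": d2})
        assert len(rep["changes"]["strength"]) == 1
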