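"""Degree-, weight- and strength-preserving null networks.

Topology is randomized with Maslov–Sneppen double-edge swaps (exact degree
sequence); the original weight multiset is then reassigned to the new links
by iterative greedy rank-matching against the original node strengths, so
each node's strength is approximately preserved.  Modular structure of the
source network is compared against the ensemble with a co-assignment-matrix
correlation (adjusted Rand index emitted alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .metrics import Partition, louvain_partition
from .network import WeightedNetwork

__all__ = [
    "NullEnsemble",
    "SimilarityReport",
    "randomize_network",
    "build_ensemble",
    "partition_similarity",
    "adjusted_rand",
    "null_comparison",
]


@dataclass
class NullEnsemble:
    source_condition: str | None
    members: list[WeightedNetwork]
    partitions: list[Partition]
    seeds: list[int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SimilarityReport:
    """Per-member similarity of the source partition to the null partitions."""

    values: tuple[float, ...]
    ari: tuple[float, ...] = field(default_factory=tuple)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def _reassign_weights(
    topology: np.ndarray, weights_sorted: np.ndarray, target_strength: np.ndarray
) -> np.ndarray:
    """Place the weight multiset on the new topology, largest weights first on
    the edges whose endpoints have the largest remaining strength budget."""
    n = topology.shape[0]
    iu = np.triu_indices(n, 1)
    on = topology[iu] > 0
    ei, ej = iu[0][on], iu[1][on]
    residual = target_strength.astype(float).copy()
    w = np.zeros((n, n))
    active = np.ones(len(ei), bool)
    for weight in weights_sorted:  # descending
        score = np.where(active, residual[ei] * residual[ej], -np.inf)
        e = int(np.argmax(score))
        i, j = ei[e], ej[e]
        w[i, j] = w[j, i] = weight
        residual[i] -= weight
        residual[j] -= weight
        active[e] = False
    return w


def randomize_network(
    net: WeightedNetwork, seed: int = 0, rewires_per_edge: int = 10
) -> WeightedNetwork:
    """One degree-, weight- and strength-preserving randomization of `net`."""
    import networkx as nx

    m = net.n_links
    if m < 4:
        warnings.warn(
            "network too small to rewire; returned unchanged", RuntimeWarning,
            stacklevel=2,
        )
        return WeightedNetwork(
            nodes=net.nodes, weights=net.weights.copy(), condition=net.condition,
            metadata={**net.metadata, "null_seed": seed, "rewired": False},
        )
    g = nx.from_numpy_array(net.weights)
    try:
        nx.double_edge_swap(
            g, nswap=rewires_per_edge * m, max_tries=100 * rewires_per_edge * m,
            seed=seed,
        )
    except nx.NetworkXException as err:
        # very dense graphs exhaust the attempt budget; the swaps already
        # performed stay in place and still randomize the topology
        warnings.warn(f"edge swapping stopped early: {err}", RuntimeWarning,
                      stacklevel=2)
    topology = (nx.to_numpy_array(g, nodelist=range(net.n_nodes)) > 0).astype(float)

    iu = np.triu_indices(net.n_nodes, 1)
    orig_weights = np.sort(net.weights[iu][net.weights[iu] > 0])[::-1]
    strength = net.weights.sum(axis=1)
    w = _reassign_weights(topology, orig_weights, strength)
    rho = sps.spearmanr(strength, w.sum(axis=1)).statistic
    return WeightedNetwork(
        nodes=net.nodes, weights=w, condition=net.condition,
        metadata={"null_seed": seed, "rewired": True,
                  "strength_spearman": float(rho)},
    )


def build_ensemble(
    net: WeightedNetwork,
    n: int = 100,
    master_seed: int = 0,
    rewires_per_edge: int = 10,
    partition_restarts: int = 20,
) -> NullEnsemble:
    """Generate `n` null members and partition each one.

    Exact preservation of the degree sequence and weight multiset is
    asserted per member.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = np.random.default_rng(master_seed)
    seeds = [int(rng.integers(2**31)) for _ in range(n)]
    iu = np.triu_indices(net.n_nodes, 1)
    deg0 = np.sort((net.weights > 0).sum(axis=1))
    w0 = np.sort(net.weights[iu][net.weights[iu] > 0])
    members, partitions = [], []
    for i, s in enumerate(seeds):
        member = randomize_network(net, seed=s, rewires_per_edge=rewires_per_edge)
        deg = np.sort((member.weights > 0).sum(axis=1))
        wts = np.sort(member.weights[iu][member.weights[iu] > 0])
        assert np.array_equal(deg, deg0), "degree sequence not preserved"
        assert np.allclose(wts, w0), "weight multiset not preserved"
        members.append(member)
        partitions.append(
            louvain_partition(member, seed=s, n_restarts=partition_restarts)
        )
    return NullEnsemble(
        source_condition=net.condition, members=members, partitions=partitions,
        seeds=seeds,
    )


def _coassignment(p: Partition) -> np.ndarray:
    labels = np.asarray(p.labels)
    iu = np.triu_indices(len(labels), 1)
    return (labels[iu[0]] == labels[iu[1]]).astype(float)


def partition_similarity(p1: Partition, p2: Partition) -> float:
    """Correlation between the two partitions' pairwise co-assignment vectors.

    Identical partitions give 1.0.  If either co-assignment vector is
    constant (a single module, or all singletons) the correlation is
    undefined: returns 1.0 when the two vectors are equal, NaN otherwise.
    """
    if p1.nodes != p2.nodes:
        raise ValueError("partitions must share the same node set")
    a, b = _coassignment(p1), _coassignment(p2)
    if a.std() == 0 or b.std() == 0:
        return 1.0 if np.array_equal(a, b) else float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between the two partitions (reference measure)."""
    from sklearn.metrics import adjusted_rand_score

    if p1.nodes != p2.nodes:
        raise ValueError("partitions must share the same node set")
    return float(adjusted_rand_score(p1.labels, p2.labels))


def null_comparison(
    net: WeightedNetwork,
    partition: Partition,
    n: int = 100,
    master_seed: int = 0,
    **ensemble_kw,
) -> SimilarityReport:
    """Similarity of `partition` to the partitions of `n` null networks."""
    if partition.nodes != net.nodes:
        raise ValueError("partition does not match the network's nodes")
    ens = build_ensemble(net, n=n, master_seed=master_seed, **ensemble_kw)
    vals = tuple(partition_similarity(partition, p) for p in ens.partitions)
    aris = tuple(adjusted_rand(partition, p) for p in ens.partitions)
    return SimilarityReport(values=vals, ari=aris)
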