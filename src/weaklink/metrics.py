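"""Weighted graph measures: degree, strength, distances, betweenness, modularity.

Distances follow D = 1 − W, so stronger links are shorter; shortest paths
minimize the sum of link distances.  Betweenness is reported unnormalized
(the raw sum over node pairs of shortest-path fractions), which on a 23-node
network yields magnitudes of order tens; a normalized column is emitted as
well.  Community structure is found with seeded Louvain plus deterministic
single-node-move refinement, best of `n_restarts`, scored by the standard
weighted Newman modularity Q.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import WeightedNetwork

__all__ = [
    "Partition",
    "degree_strength",
    "to_distance",
    "shortest_paths",
    "betweenness",
    "modularity_q",
    "louvain_partition",
    "hub_ranking",
    "node_metrics",
]

_TIE_TOL = 1e-10


@dataclass(frozen=True)
class Partition:
    """Node→module assignment with its modularity score."""

    nodes: tuple[str, ...]
    labels: tuple[int, ...]
    q: float
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.nodes):
            raise ValueError("every node needs exactly one module label")

    @property
    def n_modules(self) -> int:
        return len(set(self.labels))

    def module_of(self, name: str) -> int:
        return self.labels[self.nodes.index(name)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.nodes, self.labels))


def degree_strength(net: WeightedNetwork) -> pd.DataFrame:
    """Per-node degree (link count) and strength (sum of link weights)."""
    w = net.weights
    return pd.DataFrame(
        {"degree": (w > 0).sum(axis=1), "strength": w.sum(axis=1)},
        index=list(net.nodes),
    )


def to_distance(net: WeightedNetwork) -> np.ndarray:
    """Link distances D = 1 − W; absent links are infinitely distant."""
    w = net.weights
    n = net.n_nodes
    bad = np.argwhere(np.triu(w, 1) >= 1.0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"weight {w[i, j]:.4f} >= 1 on edge ({net.nodes[i]}, {net.nodes[j]}) "
            "gives a non-positive distance"
        )
    d = np.full((n, n), np.inf)
    d[w > 0] = 1.0 - w[w > 0]
    np.fill_diagonal(d, 0.0)
    return d


def _dijkstra_counts(d: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-source shortest-path lengths and path counts on a distance matrix.

    Path sums within `_TIE_TOL` of the minimum are counted as equally short.
    """
    n = d.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    done = np.zeros(n, bool)
    heap = [(0.0, source)]
    while heap:
        du, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        nz = np.nonzero(np.isfinite(d[u]) & ~done)[0]
        for v in nz:
            alt = du + d[u, v]
            if alt < dist[v] - _TIE_TOL:
                dist[v] = alt
                heapq.heappush(heap, (alt, v))
    counts = np.zeros(n)
    counts[source] = 1.0
    order = np.argsort(dist, kind="stable")
    for u in order:
        if not np.isfinite(dist[u]) or counts[u] == 0:
            continue
        for v in range(n):
            if v != u and np.isfinite(d[u, v]):
                if dist[u] + d[u, v] <= dist[v] + _TIE_TOL and v != source:
                    counts[v] += counts[u]
    return dist, counts


def shortest_paths(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs weighted shortest-path lengths and minimal-path counts.

    Disconnected pairs get infinite length and count 0.
    """
    d = np.asarray(d, float)
    if (d[np.isfinite(d)] < 0).any():
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    lengths = np.empty((n, n))
    counts = np.empty((n, n))
    for s in range(n):
        lengths[s], counts[s] = _dijkstra_counts(d, s)
    counts[~np.isfinite(lengths)] = 0.0
    return lengths, counts


def betweenness(net: WeightedNetwork, normalized: bool = False) -> pd.Series:
    """Shortest-path betweenness on D = 1 − W distances.

    b_v = Σ over unordered pairs (s, t), s ≠ v ≠ t, of the fraction of
    minimal-length s–t paths passing through v.  Unnormalized by default;
    `normalized=True` divides by the number of pairs (N−1)(N−2)/2.
    """
    d = to_distance(net)
    n = net.n_nodes
    lengths, counts = shortest_paths(d)
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            sigma_st = counts[s, t]
            if sigma_st == 0 or not np.isfinite(lengths[s, t]):
                continue
            for v in range(n):
                if v == s or v == t:
                    continue
                if lengths[s, v] + lengths[v, t] <= lengths[s, t] + _TIE_TOL:
                    b[v] += counts[s, v] * counts[t, v] / sigma_st
    if normalized and n > 2:
        b = b / ((n - 1) * (n - 2) / 2.0)
    return pd.Series(b, index=list(net.nodes), name="betweenness")


def modularity_q(net: WeightedNetwork, assignment) -> float:
    """Weighted Newman modularity Q = (1/2m) Σ_ij [W_ij − s_i s_j / 2m] δ(c_i, c_j)."""
    labels = _as_labels(net, assignment)
    w = net.weights
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    s = w.sum(axis=1)
    q = 0.0
    for c in set(labels):
        ii = np.nonzero(labels == c)[0]
        q += w[np.ix_(ii, ii)].sum() / two_m - (s[ii].sum() / two_m) ** 2
    return float(q)


def _as_labels(net: WeightedNetwork, assignment) -> np.ndarray:
    if isinstance(assignment, Partition):
        return np.asarray(assignment.labels)
    if isinstance(assignment, dict):
        missing = [n for n in net.nodes if n not in assignment]
        if missing:
            raise ValueError(f"assignment is missing nodes: {missing}")
        return np.asarray([assignment[n] for n in net.nodes])
    labels = np.asarray(assignment)
    if labels.shape != (net.n_nodes,):
        raise ValueError("assignment must label every node exactly once")
    return labels


def _refine_labels(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Deterministic single-node-move hill climbing on modularity."""
    n = w.shape[0]
    two_m = w.sum()
    if two_m == 0:
        return labels
    s = w.sum(axis=1)
    labels = labels.copy()
    for _ in range(200):
        improved = False
        for v in range(n):
            current = labels[v]
            # strength of v's links into each module, and module strengths
            cand = {}
            for c in set(labels) | {current}:
                members = (labels == c) & (np.arange(n) != v)
                cand[c] = w[v, members].sum() - s[v] * s[members].sum() / two_m
            best = max(cand, key=lambda c: (cand[c], -c))
            if cand[best] > cand[current] + 1e-13:
                labels[v] = best
                improved = True
        if not improved:
            break
    # canonical relabeling by first appearance
    seen: dict[int, int] = {}
    return np.asarray([seen.setdefault(c, len(seen)) for c in labels])


def louvain_partition(
    net: WeightedNetwork, seed: int = 0, n_restarts: int = 100
) -> Partition:
    """Best-of-`n_restarts` seeded Louvain with deterministic refinement.

    Repeated calls with the same seed return identical assignments.  An
    empty network yields singleton modules with Q = 0.
    """
    import networkx as nx

    n = net.n_nodes
    if net.n_links == 0:
        return Partition(
            nodes=net.nodes, labels=tuple(range(n)), q=0.0, seed=seed,
            metadata={"n_restarts": n_restarts},
        )
    g = nx.from_numpy_array(net.weights)
    best_labels: np.ndarray | None = None
    best_q = -np.inf
    for k in range(max(1, n_restarts)):
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=seed * 100003 + k
        )
        labels = np.empty(n, int)
        for m, com in enumerate(communities):
            for v in com:
                labels[v] = m
        labels = _refine_labels(net.weights, labels)
        q = modularity_q(net, labels)
        if q > best_q + 1e-13 or (
            abs(q - best_q) <= 1e-13
            and best_labels is not None
            and tuple(labels) < tuple(best_labels)
        ):
            best_q, best_labels = q, labels
    return Partition(
        nodes=net.nodes, labels=tuple(int(c) for c in best_labels), q=best_q,
        seed=seed, metadata={"n_restarts": n_restarts},
    )


def node_metrics(net: WeightedNetwork, partition: Partition | None = None) -> pd.DataFrame:
    """Combined per-node table: degree, strength, betweenness (+ module)."""
    df = degree_strength(net)
    df["betweenness"] = betweenness(net)
    df["betweenness_norm"] = betweenness(net, normalized=True)
    if partition is not None:
        df["module"] = list(partition.labels)
    return df


def hub_ranking(tables: dict[str, pd.DataFrame], top: int = 2) -> dict:
    """Rank nodes by strength and betweenness per condition; report hub changes.

    Hubs are the rank-1 and rank-2 nodes per measure (shared ranks on ties,
    displayed lexicographically).  The change summary lists, per measure,
    the condition pairs whose hub sets differ.
    """
    if not tables:
        raise ValueError("need at least one condition table")
    report: dict = {"conditions": {}, "changes": {}}
    hubs: dict[str, dict[str, list[str]]] = {}
    for cond, df in tables.items():
        entry = {}
        for measure in ("strength", "betweenness"):
            ranks = df[measure].rank(ascending=False, method="min")
            ranked = sorted(
                df.index, key=lambda nm: (ranks[nm], nm)
            )
            hub_nodes = sorted(nm for nm in df.index if ranks[nm] <= top)
            entry[measure] = {"ranking": ranked, "hubs": hub_nodes}
        report["conditions"][cond] = entry
        hubs[cond] = {m: entry[m]["hubs"] for m in ("strength", "betweenness")}
    conds = list(tables)
    for measure in ("strength", "betweenness"):
        changes = []
        for a, b in zip(conds, conds[1:]):
            if hubs[a][measure] != hubs[b][measure]:
                changes.append(
                    {"from": a, "to": b,
                     "hubs_from": hubs[a][measure], "hubs_to": hubs[b][measure]}
                )
        report["changes"][measure] = changes
    return report
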