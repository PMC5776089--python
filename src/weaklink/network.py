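"""Condition-specific weighted network estimation.

Per subject and condition, node time courses are correlated (Pearson) and
Fisher-transformed; edges are tested at the group level with a one-sample t
test on the subjects' z scores, thresholded with Benjamini–Hochberg FDR at
q = 0.05 over the 253 edges of the condition, and the surviving positive
edges keep the group-mean z as weight.  The result is an undirected graph
with only positive weights — absent links mean "failed the threshold".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import CleanSeries

__all__ = [
    "ConnectivityMatrix",
    "WeightedNetwork",
    "correlate",
    "fisher",
    "group_edge_test",
    "bh_fdr",
    "build_network",
    "build_condition_network",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's correlation matrix and its Fisher-z transform."""

    subject_id: str
    condition: str | None
    r: np.ndarray
    z: np.ndarray


@dataclass
class WeightedNetwork:
    """Undirected graph over the roster; entry 0 = no link, else positive weight."""

    nodes: tuple[str, ...]
    weights: np.ndarray  # N x N symmetric, zero diagonal
    condition: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.diag(w).any():
            raise ValueError("weight matrix must have zero diagonal")
        if (w < 0).any():
            raise ValueError("stored weights must be positive (0 = absent link)")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int((self.weights[iu] > 0).sum())

    def link_list(self) -> list[tuple[str, str, float]]:
        iu = np.triu_indices(self.n_nodes, 1)
        out = []
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w > 0:
                out.append((self.nodes[i], self.nodes[j], float(w)))
        return out

    def has_link(self, a: str, b: str) -> bool:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return self.weights[i, j] > 0

    def weight_of(self, a: str, b: str) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.weights[i, j])

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.link_list())
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.link_list(), columns=["node_i", "node_j", "weight"]
        )

    @classmethod
    def from_edge_frame(
        cls, df: pd.DataFrame, nodes: tuple[str, ...],
        condition: str | None = None, **metadata,
    ) -> "WeightedNetwork":
        idx = {n: i for i, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for r in df.itertuples():
            i, j = idx[r.node_i], idx[r.node_j]
            w[i, j] = w[j, i] = float(r.weight)
        return cls(nodes=tuple(nodes), weights=w, condition=condition,
                   metadata=dict(metadata))

    def to_json_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "condition": self.condition,
            "links": [
                {"node_i": a, "node_j": b, "weight": w} for a, b, w in self.link_list()
            ],
            "metadata": self.metadata,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "WeightedNetwork":
        d = json.loads(Path(path).read_text())
        net = cls.from_edge_frame(
            pd.DataFrame(d["links"], columns=["node_i", "node_j", "weight"]),
            nodes=tuple(d["nodes"]), condition=d.get("condition"),
        )
        net.metadata = d.get("metadata", {})
        return net


def correlate(ts: CleanSeries | np.ndarray, subject_id: str = "",
              condition: str | None = None) -> ConnectivityMatrix:
    """Pearson correlation among node time courses, with the Fisher transform."""
    if isinstance(ts, CleanSeries):
        condition = condition or ts.condition
        values = ts.values
    else:
        values = np.asarray(ts, float)
    if values.shape[0] < 4:
        raise ValueError("need at least 4 time points to correlate")
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = [int(i) for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant node time course(s) at column(s) {bad}")
    r = np.corrcoef(values.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    z[off] = np.arctanh(np.clip(r[off], -1 + 1e-15, 1 - 1e-15))
    return ConnectivityMatrix(subject_id=subject_id, condition=condition, r=r, z=z)


def fisher(r, inverse: bool = False):
    """Fisher variance-stabilizing transform z = arctanh(r) (or its inverse)."""
    r = np.asarray(r, float)
    if inverse:
        out = np.tanh(r)
    else:
        if (np.abs(r) >= 1).any():
            raise ValueError("forward Fisher transform requires |r| < 1")
        out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def group_edge_test(z_stack: np.ndarray) -> pd.DataFrame:
    """Per-edge one-sample t test of subject Fisher-z values against zero.

    `z_stack` is subjects × N × N (symmetric).  Returns one row per
    upper-triangle edge with the group-mean z, t statistic and two-sided p.
    Edges with zero variance across subjects get p = 0 if the mean is
    nonzero (degenerate branch, warned) and p = 1 otherwise.
    """
    z_stack = np.asarray(z_stack, float)
    if z_stack.ndim != 3 or z_stack.shape[1] != z_stack.shape[2]:
        raise ValueError("z_stack must be subjects x N x N")
    if z_stack.shape[0] < 3:
        raise ValueError("need at least 3 subjects for the group edge test")
    iu = np.triu_indices(z_stack.shape[1], 1)
    z = z_stack[:, iu[0], iu[1]]  # S x E
    s = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(s))
    p = 2.0 * sps.t.sf(np.abs(np.where(degenerate, 0.0, t)), s - 1)
    if degenerate.any():
        nontrivial = degenerate & (mean != 0)
        if nontrivial.any():
            warnings.warn(
                f"{int(nontrivial.sum())} edge(s) have zero variance across "
                "subjects with nonzero mean",
                RuntimeWarning, stacklevel=2,
            )
        inf_t = np.zeros_like(mean)
        inf_t[mean > 0] = np.inf
        inf_t[mean < 0] = -np.inf
        t = np.where(degenerate, inf_t, t)
        p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"i": iu[0], "j": iu[1], "mean_z": mean, "t": t, "p": p}
    )


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level `q`."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def build_network(
    mean_z: np.ndarray,
    mask: np.ndarray,
    nodes: tuple[str, ...],
    condition: str | None = None,
    q: float = 0.05,
    n_subjects: int | None = None,
) -> WeightedNetwork:
    """Assemble the thresholded positive-weight network.

    `mean_z` is the N×N group-mean Fisher-z matrix and `mask` the per-edge
    FDR rejection mask over the upper triangle (row-major order, as produced
    by `group_edge_test`).  Significant negative edges carry no link; their
    count is recorded in the metadata.
    """
    n = len(nodes)
    mean_z = np.asarray(mean_z, float)
    iu = np.triu_indices(n, 1)
    mask = np.asarray(mask, bool)
    if mask.shape != (len(iu[0]),):
        raise ValueError("mask length must equal the number of upper-triangle edges")
    vals = mean_z[iu]
    keep = mask & (vals > 0)
    n_neg = int((mask & (vals < 0)).sum())
    w = np.zeros((n, n))
    w[iu[0][keep], iu[1][keep]] = vals[keep]
    w = w + w.T
    return WeightedNetwork(
        nodes=tuple(nodes), weights=w, condition=condition,
        metadata={
            "fdr_q": q, "n_subjects": n_subjects,
            "n_negative_dropped": n_neg, "n_links": int(keep.sum()),
        },
    )


def build_condition_network(
    z_stack: np.ndarray,
    nodes: tuple[str, ...],
    condition: str | None = None,
    q: float = 0.05,
) -> WeightedNetwork:
    """Group edge test + FDR threshold + positive-weight network in one step."""
    table = group_edge_test(z_stack)
    mask = bh_fdr(table["p"].to_numpy(), q)
    n = len(nodes)
    mz = np.zeros((n, n))
    mz[table["i"], table["j"]] = table["mean_z"]
    mz = mz + mz.T
    return build_network(
        mz, mask, nodes, condition=condition, q=q, n_subjects=z_stack.shape[0]
    )
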