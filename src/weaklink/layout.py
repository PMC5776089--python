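"""Kamada–Kawai force-spring layout.

Springs connect all node pairs; the ideal spring length between two nodes
is their weighted shortest-path distance on D = 1 − W, the spring constant
is 1/d², and the total energy E = Σ k_ij (‖x_i − x_j‖ − d_ij)² / 2 is
minimized by quasi-Newton descent from a seeded circular start.  Strongly
connected node pairs therefore sit close together.  Disconnected components
are laid out separately and offset side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .metrics import shortest_paths, to_distance
from .network import WeightedNetwork

__all__ = ["LayoutResult", "kamada_kawai"]


@dataclass(frozen=True)
class LayoutResult:
    coordinates: pd.DataFrame  # index = node names, columns x, y
    energy_initial: float
    energy_final: float
    iterations: int

    def positions(self) -> dict[str, tuple[float, float]]:
        return {n: (r.x, r.y) for n, r in self.coordinates.iterrows()}


def _energy_grad(flat: np.ndarray, d: np.ndarray, k: np.ndarray):
    n = d.shape[0]
    pos = flat.reshape(n, 2)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, 1.0)
    delta = dist - d
    np.fill_diagonal(delta, 0.0)
    e = 0.25 * (k * delta**2).sum()  # each pair counted twice
    coef = k * delta / dist
    np.fill_diagonal(coef, 0.0)
    grad = (coef[:, :, None] * diff).sum(axis=1)
    return e, grad.ravel()


def _layout_component(
    d: np.ndarray, seed: int, max_iter: int = 10_000, gtol: float = 1e-4
) -> tuple[np.ndarray, float, float, int]:
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 2)), 0.0, 0.0, 0
    k = 1.0 / np.maximum(d, 1e-12) ** 2
    np.fill_diagonal(k, 0.0)
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * (np.arange(n) / n) + rng.uniform(0, 2 * np.pi)
    scale = d[np.isfinite(d) & (d > 0)].mean() if n > 1 else 1.0
    pos0 = scale * np.column_stack([np.cos(theta), np.sin(theta)])
    e0, _ = _energy_grad(pos0.ravel(), d, k)
    res = minimize(
        _energy_grad, pos0.ravel(), args=(d, k), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 0.0},
    )
    pos = res.x.reshape(n, 2)
    e1, _ = _energy_grad(res.x, d, k)
    return pos, float(e0), float(min(e0, e1)), int(res.nit)


def kamada_kawai(net: WeightedNetwork, seed: int = 0) -> LayoutResult:
    """Spring layout of the network; deterministic given `seed`."""
    import networkx as nx

    g = net.to_graph()
    lengths, _ = shortest_paths(to_distance(net))
    components = [sorted(c, key=net.nodes.index) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), net.nodes.index(c[0])))

    coords = {}
    e0_total = e1_total = 0.0
    iters = 0
    x_offset = 0.0
    for ci, comp in enumerate(components):
        ii = [net.nodes.index(nm) for nm in comp]
        d = lengths[np.ix_(ii, ii)]
        pos, e0, e1, nit = _layout_component(d, seed=seed + ci)
        pos = pos - pos.min(axis=0, keepdims=True)
        pos[:, 0] += x_offset
        width = pos[:, 0].max() - pos[:, 0].min() if len(comp) > 1 else 0.0
        x_offset += width + 1.0
        for nm, xy in zip(comp, pos):
            coords[nm] = xy
        e0_total += e0
        e1_total += e1
        iters = max(iters, nit)
    df = pd.DataFrame(
        [coords[nm] for nm in net.nodes], index=list(net.nodes), columns=["x", "y"]
    )
    if not np.isfinite(df.to_numpy()).all():
        raise RuntimeError("layout produced non-finite coordinates")
    return LayoutResult(
        coordinates=df, energy_initial=e0_total, energy_final=e1_total,
        iterations=iters,
    )
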