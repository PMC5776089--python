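import numpy as np
import pytest

from weaklink import (
    CONDITIONS,
    default_roster,
    default_truth_config,
    make_design,
    make_ground_truth,
    simulate_cohort,
)
from weaklink.network import WeightedNetwork


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def truth_cfg():
    return default_truth_config()


@pytest.fixture(scope="session")
def truths(truth_cfg):
    return {c: make_ground_truth(c, truth_cfg) for c in CONDITIONS}


@pytest.fixture(scope="session")
def small_cohort(truths):
    """Eight-subject default-noise cohort, shared across tests."""
    return simulate_cohort(n_subjects=8, truths=truths, master_seed=7)


def random_network(n_nodes, density, rng, max_weight=0.9) -> WeightedNetwork:
    """Random connected positive-weight network (weights < 1)."""
    for _ in range(200):
        w = np.zeros((n_nodes, n_nodes))
        iu = np.triu_indices(n_nodes, 1)
        on = rng.random(len(iu[0])) < density
        w[iu[0][on], iu[1][on]] = rng.uniform(0.05, max_weight, on.sum())
        w = w + w.T
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in np.nonzero(w[v] > 0)[0]:
                if u not in seen:
                    seen.add(int(u))
                    frontier.append(int(u))
        if len(seen) == n_nodes:
            return WeightedNetwork(
                nodes=tuple(f"n{i}" for i in range(n_nodes)), weights=w
            )
    raise RuntimeError("could not draw a connected network")


@pytest.fixture
def planted_net():
    """Deterministic 23-node, 3-module network resembling a condition network."""
    rng = np.random.default_rng(11)
    n = 23
    labels = np.array([0] * 10 + [1] * 8 + [2] * 5)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                w[i, j] = rng.uniform(0.4, 0.6)
            elif rng.random() < 0.35:
                w[i, j] = rng.uniform(0.1, 0.2)
    w = w + w.T
    return WeightedNetwork(nodes=tuple(f"n{i}" for i in range(n)), weights=w,
                           condition="planted"), labels
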