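"""Condition contrasts over subjects and nodes.

Three analyses: per-node strength percent change against the movement-only
baseline; per-node Friedman tests across the three conditions over subjects
(Bonferroni-corrected over the 23 nodes, exact permutation p for small
cohorts); and a two-group profile analysis of betweenness changes — a
mixed-design ANOVA whose group × condition interaction tests whether the
two groups' mean profiles are parallel, with Mauchly's sphericity test and
a Greenhouse–Geisser-corrected fallback p.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import WeightedNetwork

__all__ = [
    "ProfileResult",
    "subject_strengths",
    "percent_change",
    "friedman_statistic",
    "friedman_exact_p",
    "friedman_per_node",
    "split_nodes_by_change",
    "mauchly_test",
    "profile_analysis",
]


def subject_strengths(z_stack: np.ndarray, net: WeightedNetwork) -> pd.DataFrame:
    """Per-subject node strengths on the group network's link set.

    Each subject's Fisher-z matrix is restricted to the links of the group
    network, keeping the link topology fixed across subjects; strengths are
    the row sums of that restricted matrix.
    """
    z_stack = np.asarray(z_stack, float)
    mask = (net.weights > 0).astype(float)
    s = (z_stack * mask[None]).sum(axis=2)
    return pd.DataFrame(s, columns=list(net.nodes))


def percent_change(strength: pd.DataFrame, baseline: str = "Task") -> pd.DataFrame:
    """Per-node strength as a percentage of the baseline condition (= 100 %).

    `strength` is nodes × conditions.  Nodes with zero baseline strength are
    flagged as NaN.
    """
    if baseline not in strength.columns:
        raise ValueError(f"baseline condition {baseline!r} not in table")
    base = strength[baseline].to_numpy(float)
    out = strength.astype(float).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out.loc[:, :] = 100.0 * strength.to_numpy(float) / base[:, None]
    out[base == 0] = np.nan
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, x)


def friedman_statistic(x: np.ndarray) -> float:
    """Friedman chi-square with average-rank tie correction (n subjects × k)."""
    x = np.asarray(x, float)
    n, k = x.shape
    ranks = _rank_rows(x)
    col = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (col**2).sum() - 3.0 * n * (k + 1)
    # tie correction: average ranks shrink the statistic's denominator
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0
    return float(stat / c)


def friedman_exact_p(x: np.ndarray, max_arrangements: int = 300_000) -> float | None:
    """Exact permutation p: all per-subject rank rearrangements, or None if too many.

    Under the null every within-subject ordering is equally likely, so the
    reference distribution enumerates the distinct permutations of each
    subject's (possibly tied) rank row.
    """
    x = np.asarray(x, float)
    n, k = x.shape
    rows = []
    total = 1
    for row in _rank_rows(x):
        perms = np.unique(
            np.array(list(itertools.permutations(row))), axis=0
        )
        rows.append(perms)
        total *= len(perms)
        if total > max_arrangements:
            return None
    observed = friedman_statistic(x)
    # DP over subjects on column rank-sum vectors (statistic depends only on
    # the column sums; the tie-correction factor is permutation invariant).
    states: dict[tuple, int] = {tuple([0.0] * k): 1}
    for perms in rows:
        new: dict[tuple, int] = {}
        for state, cnt in states.items():
            base = np.asarray(state)
            for p in perms:
                key = tuple(base + p)
                new[key] = new.get(key, 0) + cnt
        states = new
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    c = 1.0 - ties / (n * k * (k**2 - 1))
    hits = 0
    for state, cnt in states.items():
        col = np.asarray(state)
        stat = 12.0 / (n * k * (k + 1)) * (col**2).sum() - 3.0 * n * (k + 1)
        stat = stat / c if c > 0 else 0.0
        if stat >= observed - 1e-9:
            hits += cnt
    return hits / total


def friedman_per_node(
    strength_by_node: dict[str, np.ndarray] | np.ndarray,
    n_nodes_for_correction: int = 23,
    node_names: list[str] | None = None,
    exact_limit: int = 300_000,
) -> pd.DataFrame:
    """Per-node Friedman test across conditions with Bonferroni correction.

    Input is either a mapping node → (subjects × conditions) array or a
    3-D array subjects × conditions × nodes.  For small cohorts the p value
    is the exact permutation tail; otherwise the chi-square approximation
    with k−1 degrees of freedom.  Bonferroni multiplies by
    `n_nodes_for_correction` (capped at 1).
    """
    if isinstance(strength_by_node, np.ndarray):
        arr = np.asarray(strength_by_node, float)
        names = node_names or [f"node_{i}" for i in range(arr.shape[2])]
        strength_by_node = {nm: arr[:, :, i] for i, nm in enumerate(names)}
    rows = []
    for name, x in strength_by_node.items():
        x = np.asarray(x, float)
        if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
            raise ValueError(f"node {name!r}: need >= 2 subjects and >= 2 conditions")
        if np.isnan(x).any():
            warnings.warn(f"node {name!r} has missing cells; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        k = x.shape[1]
        stat = friedman_statistic(x)
        p = friedman_exact_p(x, max_arrangements=exact_limit)
        method = "exact"
        if p is None:
            p = float(sps.chi2.sf(stat, k - 1))
            method = "chi2"
        rows.append(
            {"node": name, "chi2": stat, "p": p,
             "p_bonferroni": min(1.0, p * n_nodes_for_correction),
             "method": method}
        )
    return pd.DataFrame(rows).set_index("node")


def split_nodes_by_change(
    values: pd.DataFrame, contrast: tuple[str, str] = ("Task+AgonistStim", "Task")
) -> tuple[list[str], list[str]]:
    """Split nodes into (strictly increased, decreased-or-unchanged) groups.

    `values` is nodes × conditions; `contrast` is (condition, baseline).
    Ties go to the decreased-or-unchanged group.
    """
    cond, base = contrast
    for c in contrast:
        if c not in values.columns:
            raise ValueError(f"condition {c!r} not in table")
    inc = values.index[values[cond] > values[base]].tolist()
    rest = values.index[~(values[cond] > values[base])].tolist()
    return inc, rest


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal (k-1) x k contrast matrix with zero row sums."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _mauchly_from_cov(s: np.ndarray, n_eff: int, k: int) -> tuple[float, float]:
    c = _helmert_contrasts(k)
    sc = c @ s @ c.T
    tr = np.trace(sc)
    det = np.linalg.det(sc)
    if det <= 0 or tr <= 0:
        return float("nan"), float("nan")
    w = float(det / (tr / (k - 1)) ** (k - 1))
    d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * n_eff)
    chi2 = -n_eff * d * math.log(w)
    df = k * (k - 1) // 2 - 1
    return w, float(sps.chi2.sf(chi2, df))


def mauchly_test(values: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on a cases × conditions table.

    W is the determinant/trace ratio of the orthonormal-contrast covariance;
    p uses the standard chi-square approximation.  W is NaN when the
    contrast covariance is singular.
    """
    x = np.asarray(values, float)
    n, k = x.shape
    if k < 3:
        raise ValueError("need at least 3 conditions for a sphericity test")
    if n <= k:
        raise ValueError("need more cases than conditions")
    s = np.cov(x, rowvar=False, ddof=1)
    return _mauchly_from_cov(s, n - 1, k)


def _gg_epsilon(s: np.ndarray, k: int) -> float:
    c = _helmert_contrasts(k)
    sc = c @ s @ c.T
    tr = np.trace(sc)
    return float(tr**2 / ((k - 1) * np.trace(sc @ sc)))


@dataclass(frozen=True)
class ProfileResult:
    """Mixed-design ANOVA parallelism test of two groups' condition profiles."""

    group_labels: tuple[str, ...]
    f_interaction: float
    df_num: float
    df_den: float
    p_interaction: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    p_interaction_gg: float


def profile_analysis(values: np.ndarray, group) -> ProfileResult:
    """Group × condition interaction of a two-group repeated-measures design.

    `values` is cases × conditions; `group` labels each case (exactly two
    distinct labels, each with at least 2 cases).  The interaction F tests
    profile parallelism; Mauchly's W and the Greenhouse–Geisser-corrected p
    are computed from the pooled within-group covariance of the conditions.
    """
    x = np.asarray(values, float)
    group = np.asarray(group)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("values must be cases x conditions with >= 2 conditions")
    levels = sorted(set(group.tolist()), key=str)
    if len(levels) != 2:
        raise ValueError("profile analysis needs exactly two groups")
    sizes = {g: int((group == g).sum()) for g in levels}
    if min(sizes.values()) < 2:
        raise ValueError("each group needs at least 2 cases")
    n_total, k = x.shape
    n_groups = 2

    # case-centered values: removes every constant per-case profile shift
    z = x - x.mean(axis=1, keepdims=True)
    cell = np.stack([z[group == g].mean(axis=0) for g in levels])  # G x k
    ng = np.array([sizes[g] for g in levels], float)
    grand = (ng[:, None] * cell).sum(axis=0) / n_total
    ss_int = float((ng[:, None] * (cell - grand) ** 2).sum())
    resid = z.copy()
    for gi, g in enumerate(levels):
        resid[group == g] -= cell[gi]
    ss_err = float((resid**2).sum())
    df_num = (n_groups - 1) * (k - 1)
    df_den = (n_total - n_groups) * (k - 1)
    if ss_err > 0:
        f = (ss_int / df_num) / (ss_err / df_den)
    else:  # noiseless input: parallel profiles give F = 0, otherwise F -> inf
        f = 0.0 if ss_int < 1e-12 else float("inf")
    p = float(sps.f.sf(f, df_num, df_den))

    # pooled within-group covariance for sphericity and the GG correction
    s_pool = np.zeros((k, k))
    for g in levels:
        xg = x[group == g]
        s_pool += (xg.shape[0] - 1) * np.cov(xg, rowvar=False, ddof=1)
    s_pool /= n_total - n_groups
    if k >= 3:
        w, wp = _mauchly_from_cov(s_pool, n_total - n_groups, k)
        eps = _gg_epsilon(s_pool, k)
    else:
        w, wp, eps = float("nan"), float("nan"), 1.0
    p_gg = float(sps.f.sf(f, df_num * eps, df_den * eps))
    return ProfileResult(
        group_labels=tuple(str(g) for g in levels),
        f_interaction=float(f), df_num=float(df_num), df_den=float(df_den),
        p_interaction=p, mauchly_w=w, mauchly_p=wp,
        gg_epsilon=eps, p_interaction_gg=p_gg,
    )
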