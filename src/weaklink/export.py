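"""Standard-format exports: Pajek .net, GraphML, edge lists, the run report."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .layout import LayoutResult
from .metrics import Partition
from .network import WeightedNetwork
from .nulls import SimilarityReport

__all__ = [
    "export_pajek",
    "read_pajek",
    "export_graphml",
    "export_edgelist",
    "export_report",
    "validate_report",
]


def export_pajek(net: WeightedNetwork) -> str:
    """Serialize to the Pajek .net dialect (1-based ids, quoted labels).

    Weights are written with 6 decimals; `read_pajek` round-trips the text
    losslessly at that precision.
    """
    lines = [f"*Vertices {net.n_nodes}"]
    for i, name in enumerate(net.nodes, start=1):
        lines.append(f'{i} "{name}"')
    lines.append("*Edges")
    idx = {n: i for i, n in enumerate(net.nodes, start=1)}
    for a, b, w in net.link_list():
        lines.append(f"{idx[a]} {idx[b]} {w:.6f}")
    return "\n".join(lines) + "\n"


def read_pajek(text: str) -> WeightedNetwork:
    """Companion reader for `export_pajek` output."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].lower().startswith("*vertices"):
        raise ValueError("not a Pajek network: missing *Vertices header")
    n = int(lines[0].split()[1])
    names: list[str] = []
    pos = 1
    for _ in range(n):
        _, label = lines[pos].split(" ", 1)
        names.append(label.strip().strip('"'))
        pos += 1
    if pos >= len(lines) or not lines[pos].lower().startswith("*edges"):
        raise ValueError("not a Pajek network: missing *Edges section")
    pos += 1
    rows = []
    for ln in lines[pos:]:
        i, j, w = ln.split()
        rows.append((names[int(i) - 1], names[int(j) - 1], float(w)))
    return WeightedNetwork.from_edge_frame(
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]),
        nodes=tuple(names),
    )


def export_graphml(net: WeightedNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_graph(), str(path))


def export_edgelist(net: WeightedNetwork, path: str | Path) -> None:
    net.to_edge_frame().to_csv(path, sep="\t", index=False)


_REPORT_REQUIRED = {"nodes": list, "conditions": dict, "config": dict, "seeds": dict}
_CONDITION_REQUIRED = ("links", "metrics", "modules")


def export_report(
    networks: dict[str, WeightedNetwork],
    metrics: dict[str, pd.DataFrame] | None = None,
    partitions: dict[str, Partition] | None = None,
    layouts: dict[str, LayoutResult] | None = None,
    null_reports: dict[str, SimilarityReport] | None = None,
    hub_report: dict | None = None,
    stats: dict | None = None,
    config: dict | None = None,
    seeds: dict | None = None,
) -> dict:
    """Assemble the machine-readable run report (one entry per condition)."""
    metrics = metrics or {}
    partitions = partitions or {}
    layouts = layouts or {}
    null_reports = null_reports or {}
    node_sets = {tuple(n.nodes) for n in networks.values()}
    node_sets |= {tuple(p.nodes) for p in partitions.values()}
    if len(node_sets) > 1:
        raise ValueError("inconsistent node rosters across report inputs")
    nodes = list(node_sets.pop()) if node_sets else []

    conditions = {}
    for cond, net in networks.items():
        entry: dict = {
            "links": [
                {"node_i": a, "node_j": b, "weight": w} for a, b, w in net.link_list()
            ],
            "n_links": net.n_links,
            "metrics": (
                metrics[cond].reset_index(names="node").to_dict(orient="records")
                if cond in metrics else []
            ),
            "modules": (
                {"assignment": partitions[cond].as_dict(), "q": partitions[cond].q}
                if cond in partitions else {}
            ),
        }
        if cond in layouts:
            entry["layout"] = {
                n: [float(v) for v in xy]
                for n, xy in layouts[cond].positions().items()
            }
        if cond in null_reports:
            rep = null_reports[cond]
            entry["null_comparison"] = {
                "similarity": list(rep.values), "mean": rep.mean, "sd": rep.sd,
            }
        conditions[cond] = entry
    report = {
        "nodes": nodes,
        "conditions": conditions,
        "hubs": hub_report or {},
        "stats": stats or {},
        "config": config or {},
        "seeds": seeds or {},
    }
    report = json.loads(json.dumps(report, default=_to_builtin))
    validate_report(report)
    return report


def _to_builtin(obj):
    """Coerce numpy scalars/arrays to plain Python for JSON."""
    import numpy as np

    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_report(report: dict) -> None:
    """Check the report against the expected skeleton (raises on failure)."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for cond, entry in report["conditions"].items():
        for key in _CONDITION_REQUIRED:
            if key not in entry:
                raise ValueError(f"condition {cond!r} missing key {key!r}")
    json.dumps(report)  # must be serializable
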