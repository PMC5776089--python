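"""End-to-end orchestration: simulate → preprocess → networks → metrics →
null models → condition contrasts → layout → report.

`run_study` drives the whole analysis from a `RunConfig`; the intermediate
functions are importable on their own and operate purely in memory, with
file I/O kept at the edges (`write_cohort` / `read_cohort` and the stage
writers in the CLI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, DesignParadigm, make_design
from .export import export_edgelist, export_pajek, export_report
from .layout import LayoutResult, kamada_kawai
from .metrics import Partition, hub_ranking, louvain_partition, node_metrics
from .network import WeightedNetwork, build_condition_network, correlate
from .nulls import SimilarityReport, null_comparison
from .preprocess import preprocess_subject
from .roster import default_roster, load_roster, roster_names
from .stats import (
    friedman_per_node,
    percent_change,
    profile_analysis,
    split_nodes_by_change,
    subject_strengths,
)
from .synthetic import (
    NoiseConfig,
    SubjectTimeSeries,
    default_truth_config,
    make_ground_truth,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "StudyResult",
    "cohort_z_stacks",
    "analyze_cohort",
    "run_study",
    "write_cohort",
    "read_cohort",
]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    n_subjects: int = 21
    master_seed: int = 42
    low_hz: float = 0.008
    high_hz: float = 0.09
    shift_volumes: int = 2
    fdr_q: float = 0.05
    n_nulls: int = 100
    louvain_restarts: int = 100
    null_partition_restarts: int = 20
    baseline: str = "Task"
    roster_file: str | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.roster_file and not Path(cfg.roster_file).exists():
            raise FileNotFoundError(f"roster file not found: {cfg.roster_file}")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def cohort_z_stacks(
    cohort: list[SubjectTimeSeries],
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    shift_volumes: int = 2,
) -> tuple[dict[str, np.ndarray], tuple[str, ...]]:
    """Preprocess every subject and stack per-condition Fisher-z matrices."""
    stacks: dict[str, list[np.ndarray]] = {}
    nodes = cohort[0].node_names
    for ts in cohort:
        if ts.node_names != nodes:
            raise ValueError("subjects have inconsistent node rosters")
        clean = preprocess_subject(ts, low_hz, high_hz, shift_volumes)
        for cond, cs in clean.items():
            cm = correlate(cs, subject_id=ts.subject_id)
            stacks.setdefault(cond, []).append(cm.z)
    return {c: np.stack(zs) for c, zs in stacks.items()}, nodes


@dataclass
class StudyResult:
    nodes: tuple[str, ...]
    networks: dict[str, WeightedNetwork]
    z_stacks: dict[str, np.ndarray]
    metrics: dict[str, pd.DataFrame] = field(default_factory=dict)
    partitions: dict[str, Partition] = field(default_factory=dict)
    null_reports: dict[str, SimilarityReport] = field(default_factory=dict)
    layouts: dict[str, LayoutResult] = field(default_factory=dict)
    hub_report: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def analyze_cohort(
    cohort: list[SubjectTimeSeries],
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    shift_volumes: int = 2,
    fdr_q: float = 0.05,
) -> StudyResult:
    """Preprocessing plus network construction for every condition."""
    stacks, nodes = cohort_z_stacks(cohort, low_hz, high_hz, shift_volumes)
    networks = {
        cond: build_condition_network(z, nodes, condition=cond, q=fdr_q)
        for cond, z in stacks.items()
    }
    return StudyResult(nodes=nodes, networks=networks, z_stacks=stacks)


def _condition_stats(result: StudyResult, baseline: str) -> dict:
    """Strength percent change, per-node Friedman, betweenness profile analysis."""
    conds = list(result.networks)
    strength = pd.DataFrame(
        {c: result.metrics[c]["strength"] for c in conds}
    )
    pct = percent_change(strength, baseline=baseline)

    per_node = {}
    for node_i, name in enumerate(result.nodes):
        per_node[name] = np.stack(
            [
                subject_strengths(result.z_stacks[c], result.networks[c]).iloc[:, node_i]
                for c in conds
            ],
            axis=1,
        )
    friedman = friedman_per_node(per_node, n_nodes_for_correction=len(result.nodes))

    betw = pd.DataFrame({c: result.metrics[c]["betweenness"] for c in conds})
    stim = next((c for c in conds if c != baseline), conds[0])
    inc, rest = split_nodes_by_change(betw, contrast=(stim, baseline))
    profile = None
    if len(inc) >= 2 and len(rest) >= 2:
        group = np.where(betw.index.isin(inc), "increased", "decreased_or_unchanged")
        profile = profile_analysis(betw.to_numpy(float), group)
    return {
        "strength": strength.to_dict(),
        "strength_percent_of_baseline": pct.to_dict(),
        "friedman": friedman.reset_index().to_dict(orient="records"),
        "betweenness_groups": {"increased": inc, "decreased_or_unchanged": rest,
                               "contrast": [stim, baseline]},
        "profile": dataclasses.asdict(profile) if profile else None,
    }


def run_study(
    config: RunConfig,
    cohort: list[SubjectTimeSeries] | None = None,
    write: bool = True,
) -> StudyResult:
    """Execute the full pipeline; optionally persist every stage under out_dir."""
    roster = (
        load_roster(config.roster_file) if config.roster_file else default_roster()
    )
    nodes = tuple(roster_names(roster))
    if cohort is None:
        cfg = default_truth_config(nodes)
        truths = {c: make_ground_truth(c, cfg) for c in CONDITIONS}
        cohort = simulate_cohort(
            n_subjects=config.n_subjects, truths=truths,
            master_seed=config.master_seed,
        )
    result = analyze_cohort(
        cohort, config.low_hz, config.high_hz, config.shift_volumes, config.fdr_q
    )

    for cond, net in result.networks.items():
        part = louvain_partition(
            net, seed=config.master_seed, n_restarts=config.louvain_restarts
        )
        result.partitions[cond] = part
        result.metrics[cond] = node_metrics(net, part)
        result.layouts[cond] = kamada_kawai(net, seed=config.master_seed)
        result.null_reports[cond] = null_comparison(
            net, part, n=config.n_nulls, master_seed=config.master_seed,
            partition_restarts=config.null_partition_restarts,
        )
    result.hub_report = hub_ranking(result.metrics)
    result.stats = _condition_stats(result, config.baseline)
    result.report = export_report(
        networks=result.networks, metrics=result.metrics,
        partitions=result.partitions, layouts=result.layouts,
        null_reports=result.null_reports, hub_report=result.hub_report,
        stats=result.stats, config=config.to_dict(),
        seeds={"master_seed": config.master_seed},
    )
    if write and config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: StudyResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for cond, net in result.networks.items():
        tag = cond.replace("+", "_")
        export_edgelist(net, out / f"network_{tag}.tsv")
        net.write_json(out / f"network_{tag}.json")
        (out / f"network_{tag}.net").write_text(export_pajek(net))
        result.metrics[cond].reset_index(names="node").to_csv(
            out / f"metrics_{tag}.tsv", sep="\t", index=False
        )
        result.layouts[cond].coordinates.reset_index(names="name").to_csv(
            out / f"layout_{tag}.csv", index=False
        )
        rep = result.null_reports[cond]
        (out / f"nulls_{tag}.json").write_text(
            json.dumps({"similarity": list(rep.values), "mean": rep.mean,
                        "sd": rep.sd, "ari": list(rep.ari)}, indent=1)
        )
    (out / "report.json").write_text(json.dumps(result.report, indent=1))
    (out / "stats.json").write_text(json.dumps(result.stats, indent=1))


def write_cohort(
    cohort: list[SubjectTimeSeries], out_dir: str | Path,
    truths: dict | None = None,
) -> None:
    """Persist the cohort as TSV tables (time series, confounds, design)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = cohort[0].design
    df = design.to_frame()
    df.to_csv(out / "design.tsv", sep="\t", index=False)
    (out / "design_meta.json").write_text(json.dumps({"tr_s": design.tr_s}))
    for ts in cohort:
        ts.to_frame().to_csv(out / f"{ts.subject_id}_timeseries.tsv", sep="\t",
                             index=False)
        ts.confounds_frame().to_csv(out / f"{ts.subject_id}_confounds.tsv",
                                    sep="\t", index=False)
    if truths:
        for cond, truth in truths.items():
            tag = cond.replace("+", "_")
            truth.to_edge_frame().to_csv(out / f"truth_{tag}.tsv", sep="\t",
                                         index=False)


def read_cohort(in_dir: str | Path) -> list[SubjectTimeSeries]:
    """Load a cohort previously written by `write_cohort`."""
    src = Path(in_dir)
    meta = json.loads((src / "design_meta.json").read_text())
    design = DesignParadigm.from_frame(
        pd.read_csv(src / "design.tsv", sep="\t"), tr_s=float(meta["tr_s"])
    )
    cohort = []
    for ts_file in sorted(src.glob("*_timeseries.tsv")):
        sid = ts_file.name.replace("_timeseries.tsv", "")
        values = pd.read_csv(ts_file, sep="\t")
        conf = pd.read_csv(src / f"{sid}_confounds.tsv", sep="\t")
        cohort.append(
            SubjectTimeSeries(
                subject_id=sid, values=values.to_numpy(float),
                node_names=tuple(values.columns), tr_s=design.tr_s,
                confounds=conf.to_numpy(float),
                confound_names=tuple(conf.columns), design=design,
            )
        )
    if not cohort:
        raise FileNotFoundError(f"no *_timeseries.tsv files under {src}")
    return cohort
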