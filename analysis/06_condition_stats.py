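"""Condition contrasts: strength percent change vs the Task baseline,
per-node Friedman tests (Bonferroni over 23 nodes), and the two-group
profile analysis of betweenness changes with Mauchly's sphericity test.

Reads the clean segments and network/metric outputs; writes
results/stats/stats.json and a per-node TSV.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from weaklink.network import WeightedNetwork, correlate
from weaklink.stats import (
    friedman_per_node,
    percent_change,
    profile_analysis,
    split_nodes_by_change,
    subject_strengths,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clean", default="results/clean")
    ap.add_argument("--networks", default="results/networks")
    ap.add_argument("--metrics", default="results/metrics")
    ap.add_argument("--baseline", default="Task")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results/stats")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    stacks: dict[str, list[np.ndarray]] = {}
    nodes = None
    for f in sorted(Path(args.clean).glob("*_clean.tsv")):
        sid, tag = f.name.replace("_clean.tsv", "").split("_", 1)
        df = pd.read_csv(f, sep="\t")
        nodes = tuple(df.columns)
        stacks.setdefault(tag.replace("_", "+", 1), []).append(
            correlate(df.to_numpy(float), sid).z
        )
    nets = {}
    metric_tables = {}
    for f in sorted(Path(args.networks).glob("network_*.json")):
        tag = f.stem.replace("network_", "")
        cond = tag.replace("_", "+", 1)
        nets[cond] = WeightedNetwork.read_json(f)
        metric_tables[cond] = pd.read_csv(
            Path(args.metrics) / f"metrics_{tag}.tsv", sep="\t"
        ).set_index("node")
    conds = sorted(nets, key=lambda c: (c != args.baseline, c))

    strength = pd.DataFrame({c: metric_tables[c]["strength"] for c in conds})
    pct = percent_change(strength, baseline=args.baseline)
    stim = "Task+AgonistStim" if "Task+AgonistStim" in conds else conds[-1]
    top = pct[stim].sort_values(ascending=False).head(3)
    print(f"largest strength increases vs {args.baseline} under {stim}:")
    for node, v in top.items():
        print(f"  {node}: {v:.0f}% of baseline")

    per_node = {
        nm: np.stack(
            [subject_strengths(np.stack(stacks[c]), nets[c])[nm] for c in conds],
            axis=1,
        )
        for nm in nodes
    }
    fried = friedman_per_node(per_node, n_nodes_for_correction=len(nodes))
    sig = fried[fried["p_bonferroni"] < args.alpha]
    print(f"\nFriedman (strength across {len(conds)} conditions, Bonferroni x "
          f"{len(nodes)}): {len(sig)} significant node(s)")
    for node, row in sig.iterrows():
        print(f"  {node}: chi2 = {row.chi2:.2f}, corrected p = {row.p_bonferroni:.4f}")

    betw = pd.DataFrame({c: metric_tables[c]["betweenness"] for c in conds})
    inc, rest = split_nodes_by_change(betw, contrast=(stim, args.baseline))
    profile = None
    if len(inc) >= 2 and len(rest) >= 2:
        group = np.where(betw.index.isin(inc), "increased", "decreased_or_unchanged")
        profile = profile_analysis(betw.to_numpy(float), group)
        print(f"\nprofile analysis of betweenness ({len(inc)} increased vs "
              f"{len(rest)} decreased/unchanged nodes):")
        print(f"  interaction F({profile.df_num:.0f}, {profile.df_den:.0f}) = "
              f"{profile.f_interaction:.3f}, p = {profile.p_interaction:.3f}")
        print(f"  Mauchly W = {profile.mauchly_w:.3f} (p = {profile.mauchly_p:.3f}); "
              f"GG-corrected p = {profile.p_interaction_gg:.3f}")

    import dataclasses

    fried.reset_index().to_csv(out / "friedman.tsv", sep="\t", index=False)
    pct.reset_index(names="node").to_csv(out / "strength_percent.tsv", sep="\t",
                                         index=False)
    (out / "stats.json").write_text(json.dumps({
        "strength": strength.to_dict(),
        "strength_percent_of_baseline": pct.to_dict(),
        "friedman": fried.reset_index().to_dict(orient="records"),
        "betweenness_groups": {"increased": inc, "decreased_or_unchanged": rest},
        "profile": dataclasses.asdict(profile) if profile else None,
    }, indent=1))


if __name__ == "__main__":
    main()
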