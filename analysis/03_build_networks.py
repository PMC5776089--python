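"""Estimate the three condition networks: Pearson -> Fisher z -> group
one-sample t per edge -> BH-FDR (q = 0.05) -> positive-weight graph.

Reports link counts and whether the weak thalamus-M1 link survived in each
condition; writes edge lists and network JSONs under results/networks/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from weaklink.export import export_edgelist
from weaklink.network import build_condition_network, correlate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", default="results/clean")
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--out", default="results/networks")
    args = ap.parse_args()

    src = Path(args.in_dir)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    by_cond: dict[str, list[np.ndarray]] = {}
    nodes = None
    for f in sorted(src.glob("*_clean.tsv")):
        sid, tag = f.name.replace("_clean.tsv", "").split("_", 1)
        df = pd.read_csv(f, sep="\t")
        nodes = tuple(df.columns)
        by_cond.setdefault(tag, []).append(correlate(df.to_numpy(float), sid).z)

    full = len(nodes) * (len(nodes) - 1) // 2
    print(f"{len(nodes)} nodes -> {full} possible links per network")
    for tag, zs in sorted(by_cond.items()):
        cond = tag.replace("_", "+", 1)
        net = build_condition_network(np.stack(zs), nodes, condition=cond, q=args.fdr)
        export_edgelist(net, out / f"network_{tag}.tsv")
        net.write_json(out / f"network_{tag}.json")
        thal_m1 = net.weight_of("L_Thalamus", "L_M1")
        print(f"{cond}: {net.n_links} links "
              f"({net.metadata['n_negative_dropped']} significant-negative dropped); "
              f"thalamus-M1 weight = {thal_m1:.3f}"
              + ("" if thal_m1 > 0 else " (absent)"))


if __name__ == "__main__":
    main()
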