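"""Kamada-Kawai layouts, Pajek/GraphML exports and the bundled run report.

Writes per-condition coordinate CSVs and .net/.graphml files plus a single
machine-readable report.json under results/report/.
"""

import argparse
import json
from pathlib import Path

from weaklink.export import export_graphml, export_pajek, export_report
from weaklink.layout import kamada_kawai
from weaklink.metrics import louvain_partition
from weaklink.network import WeightedNetwork


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", default="results/networks")
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--out", default="results/report")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    networks, layouts, partitions = {}, {}, {}
    for f in sorted(Path(args.in_dir).glob("network_*.json")):
        tag = f.stem.replace("network_", "")
        cond = tag.replace("_", "+", 1)
        net = WeightedNetwork.read_json(f)
        res = kamada_kawai(net, seed=args.seed)
        networks[cond], layouts[cond] = net, res
        partitions[cond] = louvain_partition(net, seed=args.seed, n_restarts=100)
        res.coordinates.reset_index(names="name").to_csv(
            out / f"layout_{tag}.csv", index=False
        )
        (out / f"network_{tag}.net").write_text(export_pajek(net))
        export_graphml(net, out / f"network_{tag}.graphml")
        print(f"{cond}: spring energy {res.energy_initial:.1f} -> "
              f"{res.energy_final:.1f} ({res.iterations} iterations)")

    report = export_report(networks=networks, partitions=partitions,
                           layouts=layouts, seeds={"layout_seed": args.seed})
    (out / "report.json").write_text(json.dumps(report, indent=1))
    print(f"report written to {out / 'report.json'}")


if __name__ == "__main__":
    main()
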