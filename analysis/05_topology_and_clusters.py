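"""Topological panels, closeness centrality and module detection per network."""
import argparse
import json
from pathlib import Path

import pandas as pd

from grndiff import io as gio
from grndiff.clusters import detect_modules
from grndiff.topology import closeness_centrality, topology_summary


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    netdir = args.outdir / "networks"

    bundle = {}
    for cond in ("normal", "tumor"):
        net = gio.read_network(netdir / f"{cond}.sif", netdir / f"{cond}.attrs.tsv")
        summary = topology_summary(net)
        bundle[cond] = summary.as_dict()
        pd.Series(closeness_centrality(net), name="closeness").rename_axis(
            "node_id"
        ).to_csv(args.outdir / f"closeness_{cond}.tsv", sep="\t")
        clusters = detect_modules(net)
        rows = [
            {"cluster_id": c.cluster_id, "node_id": m, "density": round(c.density, 4)}
            for c in clusters
            for m in c.members
        ]
        pd.DataFrame(rows, columns=["cluster_id", "node_id", "density"]).to_csv(
            args.outdir / f"clusters_{cond}.tsv", sep="\t", index=False
        )
        print(f"{cond}: diameter {summary.diameter}, "
              f"characteristic path length {summary.characteristic_path_length:.2f}, "
              f"avg neighbors {summary.avg_neighbors:.2f}, "
              f"{len(clusters)} clusters > 10 nodes")
    (args.outdir / "topology.json").write_text(json.dumps(bundle, indent=2) + "\n")
    print(f"wrote topology and cluster tables to {args.outdir}")


if __name__ == "__main__":
    main()
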