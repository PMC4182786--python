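"""Score the inferred networks and lost-edge classes against planted truth.

Reads the truth table written by 01 and the inference/comparison outputs of
03-04, and reports planted-edge recovery (precision/recall on unordered
gene pairs) and lost-edge class recovery, bundling everything into the
final report JSON.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from grndiff import io as gio
from grndiff.pipeline import recovery_metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = args.outdir / "cohort"
    netdir = args.outdir / "networks"

    truth = gio.read_truth(cohort / "truth.tsv")
    tfs = gio.read_tf_list(cohort / "tf_list.txt")
    net_n = gio.read_network(netdir / "normal.sif", netdir / "normal.attrs.tsv", tfs)
    net_t = gio.read_network(netdir / "tumor.sif", netdir / "tumor.attrs.tsv", tfs)

    rec_n = recovery_metrics(net_n, truth.normal_edges)
    rec_t = recovery_metrics(net_t, truth.tumor_edges)

    changes = pd.read_csv(args.outdir / "edge_changes.tsv", sep="\t")
    compared = matched = 0
    for row in changes.itertuples(index=False):
        key = (row.regulator_id, row.target_id)
        if key in truth.lost_edge_classes:
            compared += 1
            matched += int(truth.lost_edge_classes[key] == row.edge_class)
    class_pct = 100.0 * matched / compared if compared else float("nan")

    metrics = {
        "normal_recovery": rec_n,
        "tumor_recovery": rec_t,
        "lost_class_compared": compared,
        "lost_class_recovery_pct": round(class_pct, 1),
        "edge_ratio_tumor_normal": round(net_t.n_edges / net_n.n_edges, 3),
    }
    comparison = json.loads((args.outdir / "comparison.json").read_text())
    topology = json.loads((args.outdir / "topology.json").read_text())
    gio.write_report(
        {"comparison": comparison, "topology": topology, "truth_metrics": metrics},
        args.outdir / "report.json",
    )

    print(f"normal network: precision {rec_n['precision']:.3f}, recall {rec_n['recall']:.3f}")
    print(f"tumor network:  precision {rec_t['precision']:.3f}, recall {rec_t['recall']:.3f}")
    print(f"lost-edge class recovery: {class_pct:.1f}% over {compared} planted-lost edges")
    print(f"wrote {args.outdir / 'report.json'}")


if __name__ == "__main__":
    main()
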