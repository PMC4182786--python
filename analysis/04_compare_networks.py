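"""Differential comparison: overlap, lost-edge classes, gains, mutations.

Partitions the edge universe into conserved/lost/gained, classifies every
lost edge mechanistically (silencing of TF and/or target vs decorrelation),
ranks gained connectivity, tests the mutation-frequency association on the
tumor network, and writes the descriptive comparison report.
"""
import argparse
from pathlib import Path

import pandas as pd

from grndiff import io as gio
from grndiff.compare import (
    classify_lost_edges,
    edge_status,
    mutation_degree_association,
    rank_gains,
    summarize_comparison,
)
from grndiff.expression import read_expression
from grndiff.mi import calibrate_null


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = args.outdir / "cohort"
    netdir = args.outdir / "networks"

    tfs = gio.read_tf_list(cohort / "tf_list.txt")
    net_n = gio.read_network(netdir / "normal.sif", netdir / "normal.attrs.tsv", tfs)
    net_t = gio.read_network(netdir / "tumor.sif", netdir / "tumor.attrs.tsv", tfs)
    expr = read_expression(cohort / "expression.tsv", cohort / "samples.tsv")
    expr_n, expr_t = expr.condition("normal"), expr.condition("tumor")

    calib = calibrate_null(expr_n.shape[1], n_permutations=10_000, seed=args.seed)
    status = edge_status(net_n, net_t)
    lost = sorted(e for e, s in status.items() if s == "lost")
    records = classify_lost_edges(lost, expr_n, expr_t, calib, calib)
    gains = rank_gains(net_n, net_t)
    report = summarize_comparison(net_n, net_t, records, gains).as_dict()
    report["mutation_association"] = mutation_degree_association(
        net_t, gio.read_mutation_table(cohort / "mutations.tsv")
    )

    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        args.outdir / "edge_changes.tsv", sep="\t", index=False
    )
    pd.DataFrame([r.__dict__ for r in gains.tfs + gains.targets]).to_csv(
        args.outdir / "gain_ranking.tsv", sep="\t", index=False
    )
    gio.write_report(report, args.outdir / "comparison.json")

    n_lost = sum(1 for s in status.values() if s == "lost")
    n_gain = sum(1 for s in status.values() if s == "gained")
    n_cons = sum(1 for s in status.values() if s == "conserved")
    print(f"edges: {n_lost} lost, {n_gain} gained, {n_cons} conserved")
    print("lost-edge classes (%):", report["lost_class_pct"])
    print("edge reduction:", report["reductions_pct"]["edges"], "%;",
          "ratio tumor/normal:", report["ratios"]["edges"])
    ma = report["mutation_association"]
    if ma["testable"]:
        print(f"mutation association: mean in-degree {ma['mean_in_degree_mutated']:.1f} "
              f"(mutated) vs {ma['mean_in_degree_not_mutated']:.1f}, p = {ma['p_value']:.2g}")
    print(f"wrote comparison outputs to {args.outdir}")


if __name__ == "__main__":
    main()
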