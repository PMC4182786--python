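"""End-to-end desk-scale study: simulate, filter, infer, compare, score.

The desk-scale defaults (60 TFs, 240 targets, 98 paired samples per
condition, 100 bootstrap replicates) are a 1/20-gene-scale analogue of a
~100-pair tumor/normal cohort that keeps a full run within minutes on one
CPU while preserving the statistical regime of the method: the same sample
size, log2 scale, significance threshold and consensus machinery as a
full-scale analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import ClusterResult, detect_modules
from .compare import (
    EdgeChangeRecord,
    GainRanking,
    classify_lost_edges,
    edge_status,
    rank_gains,
    summarize_comparison,
    mutation_degree_association,
)
from .expression import ExpressionMatrix
from .inference import (
    ConsensusNetwork,
    InferenceConfig,
    RegulatoryNetwork,
    bootstrap_consensus,
    orient_and_trim,
)
from .mi import MICalibration, calibrate_null
from .preprocess import ProbeFilterResult, filter_probes
from .synthetic import (
    DisruptionSpec,
    PlantedNetwork,
    PlantedTruth,
    apply_tumor_program,
    generate_grn,
    simulate_expression,
)
from .topology import TopologySummary, topology_summary

__all__ = ["DeskStudyResult", "run_desk_study", "recovery_metrics", "synthetic_mutation_table"]


def _unordered(pairs) -> set[frozenset]:
    return {frozenset(p) for p in pairs}


def recovery_metrics(net: RegulatoryNetwork, true_edges) -> dict:
    """Precision/recall of an inferred network against planted edges.

    Comparison is on unordered gene pairs: the orientation convention turns
    one planted TF-TF dependency into two reciprocal directed edges, which
    should count as one recovered interaction.
    """
    inferred = _unordered(net.undirected_pairs())
    truth = _unordered(true_edges)
    tp = len(inferred & truth)
    precision = tp / len(inferred) if inferred else 0.0
    recall = tp / len(truth) if truth else 0.0
    return {
        "n_inferred_pairs": len(inferred),
        "n_true_pairs": len(truth),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def synthetic_mutation_table(
    truth: PlantedTruth, net: PlantedNetwork, seed: int, base_rate: float = 0.1
) -> pd.Series:
    """Synthetic per-gene somatic mutation frequencies (percent).

    Gained-edge targets are enriched for high frequencies (mirroring the
    observation that frequently mutated targets attract regulation in the
    tumor network); other genes draw low frequencies.  A convenience input
    for the mutation-degree association stage; not part of the planted
    expression model.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 53)))
    gained_targets = {t for _, t in truth.gained_hub_edges}
    freqs = {}
    for g in net.gene_ids:
        if g in gained_targets and rng.random() < 0.6:
            freqs[g] = float(rng.uniform(6.0, 30.0))
        elif rng.random() < base_rate:
            freqs[g] = float(rng.uniform(5.5, 20.0))
        else:
            freqs[g] = float(rng.uniform(0.0, 5.0))
    return pd.Series(freqs, name="frequency_percent")


@dataclass
class DeskStudyResult:
    """Everything a desk-scale run produces, ready for reporting or tests."""

    planted: PlantedNetwork
    truth: PlantedTruth
    expr_normal: ExpressionMatrix
    expr_tumor: ExpressionMatrix
    probe_filter: ProbeFilterResult
    calibration: MICalibration
    consensus_normal: ConsensusNetwork
    consensus_tumor: ConsensusNetwork
    net_normal: RegulatoryNetwork
    net_tumor: RegulatoryNetwork
    edge_changes: list[EdgeChangeRecord]
    gains: GainRanking
    topology_normal: TopologySummary
    topology_tumor: TopologySummary
    clusters_normal: list[ClusterResult]
    clusters_tumor: list[ClusterResult]
    report: dict
    metrics: dict


def run_desk_study(
    seed: int = 0,
    n_tfs: int = 60,
    n_targets: int = 240,
    n_samples: int = 98,
    mean_out_degree: float = 6.0,
    noise_sd: float = 1.0,
    n_inert: int = 60,
    n_saturated: int = 10,
    n_bootstrap: int = 100,
    n_permutations: int = 10_000,
    disruption: DisruptionSpec | None = None,
    mutation_table: pd.Series | None = None,
) -> DeskStudyResult:
    """Run the full analysis chain on one synthetic paired cohort.

    Stages: planted network -> paired normal/tumor matrices -> probe filter
    on the pooled matrix -> kernel-width and null calibration at the
    per-condition sample size -> bootstrap consensus network per condition ->
    orientation and giant component -> differential comparison (overlaps,
    lost-edge classes, gains, mutation association) -> topology and module
    summaries.  ``metrics`` scores each stage against the planted truth.
    """
    disruption = disruption if disruption is not None else DisruptionSpec(seed=seed)
    planted = generate_grn(
        n_tfs,
        n_targets,
        mean_out_degree,
        seed=seed,
        n_inert=n_inert,
        n_saturated=n_saturated,
    )
    expr_n = simulate_expression(planted, n_samples, noise_sd, seed=seed * 2 + 1)
    expr_t, truth = apply_tumor_program(planted, disruption, n_samples, seed=seed * 2 + 2, noise_sd=noise_sd)

    # four components: background, saturated, expressed, and the wide-spread
    # population that tumor-silenced genes form in the pooled matrix
    pooled = ExpressionMatrix.concat([expr_n, expr_t])
    probe_filter = filter_probes(pooled, n_components=4, seed=seed)
    kept = probe_filter.kept_genes()
    expr_n_f = expr_n.subset_genes(kept)
    expr_t_f = expr_t.subset_genes(kept)
    tf_ids = [t for t in planted.tf_ids if t in set(kept)]

    calib = calibrate_null(n_samples, n_permutations=n_permutations, seed=seed)
    config = InferenceConfig(n_bootstrap=n_bootstrap, seed=seed)
    cons_n = bootstrap_consensus(expr_n_f.values, tf_ids, calib, config)
    cons_t = bootstrap_consensus(expr_t_f.values, tf_ids, calib, config)
    net_n = orient_and_trim(cons_n, tf_ids)
    net_t = orient_and_trim(cons_t, tf_ids)

    status = edge_status(net_n, net_t)
    lost = sorted(e for e, s in status.items() if s == "lost")
    records = classify_lost_edges(lost, expr_n, expr_t, calib, calib)
    gains = rank_gains(net_n, net_t)
    report_obj = summarize_comparison(net_n, net_t, records, gains)
    topo_n = topology_summary(net_n)
    topo_t = topology_summary(net_t)
    clus_n = detect_modules(net_n)
    clus_t = detect_modules(net_t)

    if mutation_table is None:
        mutation_table = synthetic_mutation_table(truth, planted, seed)
    mutation = mutation_degree_association(net_t, mutation_table)

    rec_n = recovery_metrics(net_n, truth.normal_edges)
    rec_t = recovery_metrics(net_t, truth.tumor_edges)

    # lost-edge class recovery on planted-lost edges that inference also lost
    truth_lost = truth.lost_edge_classes
    compared = matched = 0
    for r in records:
        key = (r.regulator_id, r.target_id)
        if key in truth_lost:
            compared += 1
            matched += int(truth_lost[key] == r.edge_class)
    class_recovery = 100.0 * matched / compared if compared else float("nan")

    metrics = {
        "normal_recovery": rec_n,
        "tumor_recovery": rec_t,
        "lost_class_compared": compared,
        "lost_class_matched": matched,
        "lost_class_recovery_pct": class_recovery,
        "edge_ratio_tumor_normal": net_t.n_edges / net_n.n_edges if net_n.n_edges else float("nan"),
        "planted_disrupted_fraction": disruption.disrupted_fraction,
    }

    report = {
        "comparison": report_obj.as_dict(),
        "topology": {"normal": topo_n.as_dict(), "tumor": topo_t.as_dict()},
        "clusters": {
            "normal": [c.members for c in clus_n],
            "tumor": [c.members for c in clus_t],
        },
        "mutation_association": mutation,
        "probe_filter": probe_filter.counts(),
        "calibration": {
            "n_samples": calib.n_samples,
            "kernel_width": calib.h,
            "mi_threshold_p1e-07": calib.mi_threshold(config.p_threshold),
            "null_tail_slope": calib.slope,
        },
        "config": {
            "n_bootstrap": config.n_bootstrap,
            "p_threshold": config.p_threshold,
            "dpi_tolerance": config.dpi_tolerance,
            "consensus_alpha": config.consensus_alpha,
            "seed": seed,
        },
        "metrics": metrics,
    }
    return DeskStudyResult(
        planted=planted,
        truth=truth,
        expr_normal=expr_n,
        expr_tumor=expr_t,
        probe_filter=probe_filter,
        calibration=calib,
        consensus_normal=cons_n,
        consensus_tumor=cons_t,
        net_normal=net_n,
        net_tumor=net_t,
        edge_changes=records,
        gains=gains,
        topology_normal=topo_n,
        topology_tumor=topo_t,
        clusters_normal=clus_n,
        clusters_tumor=clus_t,
        report=report,
        metrics=metrics,
    )
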