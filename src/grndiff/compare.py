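"""Differential analysis of two condition-specific regulatory networks.

Edges are identified by their directed (regulator, target) pair; the edge
universe of the comparison is the union of both giant-component networks.
Lost edges (present in normal only) are mechanistically classified from the
silencing rule -- a gene is silenced in the tumor when its mean log2
expression falls below 4 AND its tumor-minus-normal log2 fold change falls
below -1, both strict:

* class A: TF and target both silenced,
* class B: target silenced only,
* class C: TF silenced only,
* class D: neither (pure decorrelation).

Gains are ranked per node (out-degree for TFs, in-degree for targets) over
the nodes present in both networks, and the association between somatic
mutation frequency and tumor in-degree is tested with a two-sided
Mann-Whitney U.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .inference import RegulatoryNetwork
from .mi import MICalibration, copula_matrix, kernel_stack
from .expression import ExpressionMatrix

__all__ = [
    "EdgeChangeRecord",
    "GainRecord",
    "GainRanking",
    "ComparisonReport",
    "round_half_away",
    "edge_status",
    "overlap",
    "classify_lost_edges",
    "rank_gains",
    "mutation_degree_association",
    "summarize_comparison",
]

Edge = tuple[str, str]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed summaries)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class EdgeChangeRecord:
    regulator_id: str
    target_id: str
    status: str  # lost | gained | conserved
    mi_normal: float
    mi_tumor: float
    delta_mi: float
    tf_log2fc: float
    target_log2fc: float
    tf_silenced: bool
    target_silenced: bool
    edge_class: str  # A/B/C/D for lost edges, "not_applicable" otherwise


@dataclass(frozen=True)
class GainRecord:
    node_id: str
    role: str  # tf | target
    degree_normal: int
    degree_tumor: int
    gained: int
    ratio: float


@dataclass(frozen=True)
class GainRanking:
    tfs: tuple[GainRecord, ...]
    targets: tuple[GainRecord, ...]

    def summary(self) -> dict:
        out = {}
        for role, records in (("tf", self.tfs), ("target", self.targets)):
            gains = [r.gained for r in records]
            out[role] = {
                "n_nodes": len(records),
                "total_gained": int(sum(gains)),
                "mean_gained": round_half_away(float(np.mean(gains)), 1) if gains else 0.0,
                "median_gained": float(np.median(gains)) if gains else 0.0,
            }
        return out


def edge_status(net_normal: RegulatoryNetwork, net_tumor: RegulatoryNetwork) -> dict[Edge, str]:
    """Partition the union of directed edges into conserved/lost/gained."""
    e_n = net_normal.directed_edges()
    e_t = net_tumor.directed_edges()
    status = {e: "conserved" for e in e_n & e_t}
    status.update({e: "lost" for e in e_n - e_t})
    status.update({e: "gained" for e in e_t - e_n})
    return status


def overlap(net_normal: RegulatoryNetwork, net_tumor: RegulatoryNetwork) -> dict:
    """Node and edge overlap, with percentages relative to the tumor network."""
    if net_normal.n_edges == 0 or net_tumor.n_edges == 0:
        raise ValueError("both networks must be nonempty")
    nodes_n, nodes_t = set(net_normal.graph), set(net_tumor.graph)
    edges_n, edges_t = net_normal.directed_edges(), net_tumor.directed_edges()
    shared_nodes = nodes_n & nodes_t
    shared_edges = edges_n & edges_t
    return {
        "n_nodes_normal": len(nodes_n),
        "n_nodes_tumor": len(nodes_t),
        "shared_nodes": len(shared_nodes),
        "shared_node_pct_of_tumor": round_half_away(100.0 * len(shared_nodes) / len(nodes_t), 1),
        "n_edges_normal": len(edges_n),
        "n_edges_tumor": len(edges_t),
        "shared_edges": len(shared_edges),
        "shared_edge_pct_of_tumor": round_half_away(100.0 * len(shared_edges) / len(edges_t), 1),
    }


def _batch_mi(
    pairs: Sequence[Edge], expr: pd.DataFrame, h: float
) -> dict[Edge, float]:
    """Kernel MI for a list of gene pairs, sharing per-gene kernels."""
    genes = sorted({g for e in pairs for g in e})
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    sub = expr.loc[genes]
    pos = {g: i for i, g in enumerate(genes)}
    u = copula_matrix(sub.to_numpy(dtype=float))
    k, s = kernel_stack(u, h)
    n = u.shape[1]
    out: dict[Edge, float] = {}
    for a, b in pairs:
        ia, ib = pos[a], pos[b]
        joint = (k[ia] * k[ib]).sum(axis=1)
        mi = float(np.log(n * joint / (s[ia] * s[ib])).mean())
        out[(a, b)] = max(mi, 0.0)
    return out


def classify_lost_edges(
    lost: Iterable[Edge],
    expr_normal: ExpressionMatrix | pd.DataFrame,
    expr_tumor: ExpressionMatrix | pd.DataFrame,
    calib_normal: MICalibration,
    calib_tumor: MICalibration,
    silencing_mean_max: float = 4.0,
    silencing_log2fc_max: float = -1.0,
) -> list[EdgeChangeRecord]:
    """Mechanistic classification of lost edges.

    Silencing is strict on both thresholds: mean tumor expression < 4 AND
    log2 fold change (tumor - normal means) < -1; a gene sitting exactly on
    a threshold is not silenced.  MI in each condition is re-estimated from
    the expression data with that condition's calibrated kernel width (the
    edge need not be present in either consensus network).
    """
    lost = sorted(set(lost))
    v_n = expr_normal.values if isinstance(expr_normal, ExpressionMatrix) else expr_normal
    v_t = expr_tumor.values if isinstance(expr_tumor, ExpressionMatrix) else expr_tumor
    for reg, tgt in lost:
        for g in (reg, tgt):
            if g not in v_n.index or g not in v_t.index:
                raise KeyError(f"gene {g} missing from an expression matrix")
    if not lost:
        return []
    mi_n = _batch_mi(lost, v_n, calib_normal.h)
    mi_t = _batch_mi(lost, v_t, calib_tumor.h)
    mean_n = v_n.mean(axis=1)
    mean_t = v_t.mean(axis=1)

    def silenced(g: str) -> bool:
        return bool(
            mean_t[g] < silencing_mean_max
            and (mean_t[g] - mean_n[g]) < silencing_log2fc_max
        )

    records = []
    for reg, tgt in lost:
        s_tf, s_tgt = silenced(reg), silenced(tgt)
        cls = "A" if (s_tf and s_tgt) else "B" if s_tgt else "C" if s_tf else "D"
        records.append(
            EdgeChangeRecord(
                regulator_id=reg,
                target_id=tgt,
                status="lost",
                mi_normal=mi_n[(reg, tgt)],
                mi_tumor=mi_t[(reg, tgt)],
                delta_mi=mi_t[(reg, tgt)] - mi_n[(reg, tgt)],
                tf_log2fc=float(mean_t[reg] - mean_n[reg]),
                target_log2fc=float(mean_t[tgt] - mean_n[tgt]),
                tf_silenced=s_tf,
                target_silenced=s_tgt,
                edge_class=cls,
            )
        )
    return records


def rank_gains(net_normal: RegulatoryNetwork, net_tumor: RegulatoryNetwork) -> GainRanking:
    """Nodes with increased connectivity, restricted to shared nodes.

    TFs are ranked by gained out-degree, targets by gained in-degree, ties
    by tumor/normal degree ratio then identifier.  A node absent from either
    network is excluded.  Only strictly positive gains are listed.
    """
    shared = set(net_normal.graph) & set(net_tumor.graph)

    def build(role: str) -> tuple[GainRecord, ...]:
        deg_n = dict(
            net_normal.graph.out_degree() if role == "tf" else net_normal.graph.in_degree()
        )
        deg_t = dict(
            net_tumor.graph.out_degree() if role == "tf" else net_tumor.graph.in_degree()
        )
        records = []
        for node in shared:
            dn, dt = deg_n.get(node, 0), deg_t.get(node, 0)
            if role == "tf" and not net_normal.graph.nodes[node].get("is_tf", False):
                continue
            if dt <= dn:
                continue
            ratio = dt / dn if dn > 0 else float("inf")
            records.append(
                GainRecord(
                    node_id=node,
                    role=role,
                    degree_normal=dn,
                    degree_tumor=dt,
                    gained=dt - dn,
                    ratio=ratio,
                )
            )
        records.sort(key=lambda r: (-r.gained, -r.ratio, r.node_id))
        return tuple(records)

    return GainRanking(tfs=build("tf"), targets=build("target"))


def mutation_degree_association(
    net: RegulatoryNetwork,
    mutation_freq: Mapping[str, float] | pd.Series,
    freq_threshold: float = 5.0,
) -> dict:
    """Mutated versus non-mutated target in-degree comparison.

    Target nodes (in-degree >= 1) are split at mutation frequency strictly
    greater than ``freq_threshold`` percent; group mean in-degrees are
    reported with a two-sided Mann-Whitney U test.  If either group is
    empty the result is flagged untestable.
    """
    freq = pd.Series(mutation_freq, dtype=float)
    deg = dict(net.graph.in_degree())
    targets = [n for n, d in deg.items() if d >= 1]
    mutated = [deg[n] for n in targets if freq.get(n, 0.0) > freq_threshold]
    other = [deg[n] for n in targets if not freq.get(n, 0.0) > freq_threshold]
    result = {
        "n_mutated": len(mutated),
        "n_not_mutated": len(other),
        "mean_in_degree_mutated": float(np.mean(mutated)) if mutated else float("nan"),
        "mean_in_degree_not_mutated": float(np.mean(other)) if other else float("nan"),
        "testable": bool(mutated and other),
        "u_statistic": float("nan"),
        "p_value": float("nan"),
    }
    if result["testable"]:
        u, p = mannwhitneyu(mutated, other, alternative="two-sided")
        result["u_statistic"] = float(u)
        result["p_value"] = float(p)
    return result


@dataclass(frozen=True)
class ComparisonReport:
    """The descriptive comparison panel of the two networks.

    All percentages and ratios are recomputable from the stored integer
    counts; ratios are tumor/normal to 2 decimals, reductions to the nearest
    integer percent, class percentages to 1 decimal (all half away from
    zero).
    """

    counts_normal: dict
    counts_tumor: dict
    ratios: dict
    reductions_pct: dict
    lost_class_counts: dict
    lost_class_pct: dict
    gain_summary: dict
    overlap: dict

    def as_dict(self) -> dict:
        return asdict(self)


def _network_counts(net: RegulatoryNetwork) -> dict:
    return {
        "nodes": net.n_nodes,
        "tfs": len(net.tf_nodes),
        "targets": len(net.target_nodes),
        "edges": net.n_edges,
    }


def summarize_comparison(
    net_normal: RegulatoryNetwork,
    net_tumor: RegulatoryNetwork,
    edge_changes: Sequence[EdgeChangeRecord],
    gains: GainRanking,
) -> ComparisonReport:
    c_n = _network_counts(net_normal)
    c_t = _network_counts(net_tumor)
    ratios = {
        k: round_half_away(c_t[k] / c_n[k], 2) if c_n[k] else float("nan") for k in c_n
    }
    reductions = {
        k: round_half_away(100.0 * (1.0 - c_t[k] / c_n[k])) if c_n[k] else float("nan")
        for k in c_n
    }
    lost = [r for r in edge_changes if r.status == "lost"]
    class_counts = {c: sum(1 for r in lost if r.edge_class == c) for c in "ABCD"}
    total_lost = sum(class_counts.values())
    class_pct = {
        c: round_half_away(100.0 * k / total_lost, 1) if total_lost else 0.0
        for c, k in class_counts.items()
    }
    return ComparisonReport(
        counts_normal=c_n,
        counts_tumor=c_t,
        ratios=ratios,
        reductions_pct=reductions,
        lost_class_counts=class_counts,
        lost_class_pct=class_pct,
        gain_summary=gains.summary(),
        overlap=overlap(net_normal, net_tumor),
    )
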