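"""File formats, configuration and run logging.

All tabular formats are UTF-8 tab-separated files with a mandatory header
row and no quoting.  Networks travel as a SIF file (``regulator TAB
"regulates" TAB target``) plus an attribute table (regulator, target, mi,
support, consensus_p); ground-truth tables, TF lists and mutation tables
are plain TSV/text.  Pipeline configuration is YAML and validated on load.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .expression import ExpressionMatrix, read_expression, write_expression  # noqa: F401
from .inference import InferenceConfig, RegulatoryNetwork
from .synthetic import DisruptionSpec, PlantedTruth

__all__ = [
    "PipelineConfig",
    "read_tf_list",
    "write_tf_list",
    "read_mutation_table",
    "write_mutation_table",
    "write_network",
    "read_network",
    "write_truth",
    "read_truth",
    "write_report",
]


def read_tf_list(path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    text = Path(path).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_tf_list(tf_ids, path) -> None:
    Path(path).write_text("\n".join(tf_ids) + "\n", encoding="utf-8")


def read_mutation_table(path) -> pd.Series:
    """TSV with columns gene_id, frequency_percent -> Series keyed by gene."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "frequency_percent"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df.set_index("gene_id")["frequency_percent"].astype(float)


def write_mutation_table(freq: pd.Series, path) -> None:
    df = freq.rename("frequency_percent").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def write_network(net: RegulatoryNetwork, sif_path, attr_path) -> None:
    """SIF plus edge-attribute TSV, rows sorted for byte-stable output."""
    edges = sorted(net.graph.edges(data=True))
    with open(sif_path, "w", encoding="utf-8") as fh:
        for a, b, _ in edges:
            fh.write(f"{a}\tregulates\t{b}\n")
    rows = [
        {
            "regulator": a,
            "target": b,
            "mi": f"{d['mi']:.8g}",
            "support": d.get("support", 1),
            "consensus_p": f"{d.get('consensus_p', float('nan')):.6g}",
        }
        for a, b, d in edges
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "mi", "support", "consensus_p"]).to_csv(
        attr_path, sep="\t", index=False
    )


def read_network(sif_path, attr_path, tf_ids=None) -> RegulatoryNetwork:
    g = nx.DiGraph()
    with open(sif_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] != "regulates":
                raise ValueError(f"{sif_path}:{lineno}: malformed SIF line {line!r}")
            g.add_edge(parts[0], parts[2])
    attrs = pd.read_csv(attr_path, sep="\t")
    mismatch = {(r, t) for r, t in zip(attrs["regulator"], attrs["target"])} ^ set(g.edges())
    if mismatch:
        raise ValueError(
            f"identifier mismatch between {Path(sif_path).name} and "
            f"{Path(attr_path).name}: {sorted(mismatch)[:10]}"
        )
    for row in attrs.itertuples(index=False):
        g.edges[row.regulator, row.target].update(
            mi=float(row.mi), support=int(row.support), consensus_p=float(row.consensus_p)
        )
    tf_set = set(tf_ids) if tf_ids is not None else {a for a, _ in g.edges()}
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tf_set
    return RegulatoryNetwork(g)


def write_truth(truth: PlantedTruth, path) -> None:
    """Ground-truth edge table: edge, condition membership, loss class."""
    rows = []
    for r, t in sorted(truth.normal_edges | truth.tumor_edges):
        rows.append(
            {
                "regulator": r,
                "target": t,
                "in_normal": int((r, t) in truth.normal_edges),
                "in_tumor": int((r, t) in truth.tumor_edges),
                "lost_class": truth.lost_edge_classes.get((r, t), ""),
                "gained_hub_edge": int((r, t) in truth.gained_hub_edges),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    normal = frozenset(
        (r.regulator, r.target) for r in df.itertuples(index=False) if r.in_normal
    )
    tumor = frozenset(
        (r.regulator, r.target) for r in df.itertuples(index=False) if r.in_tumor
    )
    classes = {
        (r.regulator, r.target): r.lost_class
        for r in df.itertuples(index=False)
        if r.lost_class
    }
    gained = frozenset(
        (r.regulator, r.target) for r in df.itertuples(index=False) if r.gained_hub_edge
    )
    return PlantedTruth(
        normal_edges=normal, tumor_edges=tumor, lost_edge_classes=classes, gained_hub_edges=gained
    )


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class PipelineConfig:
    """Every fixed constant of the pipeline, validated on load.

    Inference constants follow :class:`InferenceConfig`; the silencing rule
    (mean < 4, log2 FC < -1), the mutation-frequency cut (> 5%) and the
    cluster size filter (> 10 nodes) are the comparison-stage thresholds.
    """

    inference: InferenceConfig = field(default_factory=InferenceConfig)
    silencing_mean_max: float = 4.0
    silencing_log2fc_max: float = -1.0
    mutation_freq_threshold: float = 5.0
    cluster_min_size: int = 11
    n_permutations: int = 10_000
    disruption: DisruptionSpec = field(default_factory=DisruptionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_min_size < 1:
            raise ValueError("cluster_min_size must be >= 1")
        if self.n_permutations < 1000:
            raise ValueError("n_permutations must be >= 1000")
        if not 0 < self.mutation_freq_threshold < 100:
            raise ValueError("mutation_freq_threshold must be a percentage in (0, 100)")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        inference = InferenceConfig(**raw.pop("inference", {}))
        disruption = DisruptionSpec(**raw.pop("disruption", {}))
        return cls(inference=inference, disruption=disruption, **raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.as_dict(), sort_keys=True), encoding="utf-8"
        )
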