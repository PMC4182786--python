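"""ARACNe-style regulatory-network inference.

One network per condition: kernel MI is computed for every TF-gene candidate
pair, thresholded against the calibrated null at a stringent p-value, pruned
with the data processing inequality (DPI), and stabilised by bootstrap
resampling of samples with a Poisson consensus model over edge support.
The consensus edge set is finally oriented TF -> target and reduced to its
giant weakly connected component.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import poisson

from .mi import MICalibration, copula_matrix, kernel_stack, pairwise_mi_against

__all__ = [
    "InferenceConfig",
    "ConsensusEdge",
    "ConsensusNetwork",
    "RegulatoryNetwork",
    "EmptyNetworkError",
    "apply_dpi",
    "infer_single_network",
    "bootstrap_consensus",
    "orient_and_trim",
]

Pair = tuple[str, str]


class EmptyNetworkError(ValueError):
    """Raised when an operation requires a nonempty network."""


@dataclass(frozen=True)
class InferenceConfig:
    """Fixed constants of the inference run.

    ``p_threshold`` is the per-pair MI significance level, ``dpi_tolerance``
    the DPI slack (0 removes the most indirect edges), ``n_bootstrap`` the
    number of resampled inferences and ``consensus_alpha`` the family-wise
    level of the Poisson consensus test (Bonferroni over distinct observed
    edges).
    """

    p_threshold: float = 1e-07
    dpi_tolerance: float = 0.0
    n_bootstrap: int = 1000
    consensus_alpha: float = 0.05
    #: a consensus edge must additionally be significant in at least this
    #: fraction of replicates (its median replicate MI beats the threshold);
    #: guards against weakly dependent pairs whose detection rate is lifted
    #: by the tied-rank MI inflation of bootstrap resampling
    min_support_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.dpi_tolerance < 0:
            raise ValueError("dpi_tolerance must be >= 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.consensus_alpha < 1.0:
            raise ValueError("consensus_alpha must be in (0, 1)")
        if not 0.0 <= self.min_support_fraction <= 1.0:
            raise ValueError("min_support_fraction must be in [0, 1]")


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def apply_dpi(edges: Mapping[Pair, float], tolerance: float = 0.0) -> dict[Pair, float]:
    """Data-processing-inequality pruning of a weighted undirected edge set.

    For every triangle the weakest edge is marked as indirect and removed when
    ``mi * (1 + tolerance) <= min(mi of the other two edges)``; at tolerance 0
    this removes every triangle minimum, and as the tolerance grows nothing is
    removed.  A triangle's strictly strongest edge can never be marked.
    Marking is a single pass over all triangles followed by one deletion, so
    the result does not depend on edge order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    adj: dict[str, set[str]] = defaultdict(set)
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    doomed: set[Pair] = set()
    for (a, b), mi_ab in edges.items():
        for c in adj[a] & adj[b]:
            mi_ac = edges[_pair(a, c)]
            mi_bc = edges[_pair(b, c)]
            if mi_ab * (1.0 + tolerance) <= min(mi_ac, mi_bc):
                doomed.add(_pair(a, b))
                break
    return {e: m for e, m in edges.items() if e not in doomed}


def _infer_from_values(
    values: np.ndarray,
    gene_ids: list[str],
    tf_positions: list[int],
    mi_min: float,
    dpi_tolerance: float,
    h: float,
) -> dict[Pair, float]:
    """Significant post-DPI TF-gene edge set for one expression matrix.

    Candidate pairs are TF versus every other gene; TF-TF pairs are scored
    once per unordered pair.  Per-gene kernel matrices are shared across all
    pairs they participate in.
    """
    n = values.shape[1]
    u = copula_matrix(values)
    k, s = kernel_stack(u, h)
    tf_set = set(tf_positions)
    sig: dict[Pair, float] = {}
    for rank, t in enumerate(tf_positions):
        partners = [
            g
            for g in range(len(gene_ids))
            if g != t and (g not in tf_set or g in tf_positions[rank + 1 :])
        ]
        if not partners:
            continue
        mis = pairwise_mi_against(k[t], s[t], k[partners], s[partners])
        for g, m in zip(partners, mis):
            if m >= mi_min:
                sig[_pair(gene_ids[t], gene_ids[g])] = float(m)
    return apply_dpi(sig, dpi_tolerance)


def infer_single_network(
    expr: pd.DataFrame,
    tf_ids: Iterable[str],
    calib: MICalibration,
    config: InferenceConfig,
) -> dict[Pair, float]:
    """Single-run significant edge set (undirected pairs -> MI in nats).

    MI is estimated for TF-gene pairs only, kept when it reaches the
    calibrated threshold at ``config.p_threshold``, and DPI-pruned.
    """
    gene_ids = list(expr.index)
    tf_positions = [i for i, g in enumerate(gene_ids) if g in set(tf_ids)]
    if not tf_positions:
        raise ValueError("no transcription factor from tf_ids is present in expr")
    mi_min = calib.mi_threshold(config.p_threshold)
    return _infer_from_values(
        expr.to_numpy(dtype=float),
        gene_ids,
        tf_positions,
        mi_min,
        config.dpi_tolerance,
        calib.h,
    )


@dataclass(frozen=True)
class ConsensusEdge:
    mi: float
    support: int
    consensus_p: float


@dataclass(frozen=True)
class ConsensusNetwork:
    """Bootstrap consensus over undirected significant edges.

    ``edges`` keeps, per retained unordered pair, the mean MI over supporting
    replicates, the support count and the Poisson tail p-value.  ``lam`` is
    the chance-model rate (total detections / distinct edges observed).
    """

    edges: dict[Pair, ConsensusEdge]
    n_bootstrap: int
    lam: float
    n_distinct_observed: int


def poisson_tail(k: int, lam: float) -> float:
    """P(Poisson(lam) >= k)."""
    return float(poisson.sf(k - 1, lam))


def bootstrap_consensus(
    expr: pd.DataFrame,
    tf_ids: Iterable[str],
    calib: MICalibration,
    config: InferenceConfig,
    replicate_calib: MICalibration | None = None,
) -> ConsensusNetwork:
    """Consensus network from B bootstrap resamples of samples.

    Each replicate resamples columns with replacement and re-runs the single
    network inference.  Resampling duplicates joint observations, which
    inflates the kernel MI of even independent pairs, so the per-replicate
    threshold is taken from ``replicate_calib`` when given -- a null
    calibrated under the same resampling scheme
    (``calibrate_null(..., resampled=True)``).  Under the consensus chance
    model every detection falls on a random observed edge, so per-edge
    support is Poisson with rate ``lam = total detections / distinct
    edges``; edges are retained when their Poisson tail p-value beats
    ``consensus_alpha`` Bonferroni-corrected for the number of distinct
    edges observed.  Deterministic for a fixed seed.
    """
    gene_ids = list(expr.index)
    tf_positions = [i for i, g in enumerate(gene_ids) if g in set(tf_ids)]
    if not tf_positions:
        raise ValueError("no transcription factor from tf_ids is present in expr")
    values = expr.to_numpy(dtype=float)
    n = values.shape[1]
    mi_min = (replicate_calib or calib).mi_threshold(config.p_threshold)
    support: dict[Pair, int] = defaultdict(int)
    mi_sum: dict[Pair, float] = defaultdict(float)
    children = np.random.SeedSequence(config.seed).spawn(config.n_bootstrap)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        edges = _infer_from_values(
            values[:, idx], gene_ids, tf_positions, mi_min, config.dpi_tolerance, calib.h
        )
        for pair, m in edges.items():
            support[pair] += 1
            mi_sum[pair] += m
    if not support:
        return ConsensusNetwork({}, config.n_bootstrap, 0.0, 0)
    distinct = len(support)
    lam = sum(support.values()) / distinct
    cutoff = config.consensus_alpha / distinct
    floor = int(np.ceil(config.min_support_fraction * config.n_bootstrap))
    kept = {
        pair: ConsensusEdge(mi_sum[pair] / k, k, poisson_tail(k, lam))
        for pair, k in support.items()
        if poisson_tail(k, lam) < cutoff and k >= floor
    }
    return ConsensusNetwork(kept, config.n_bootstrap, lam, distinct)


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target network (giant component of a consensus).

    Backed by a ``networkx.DiGraph`` whose nodes carry ``is_tf`` and whose
    edges carry ``mi``, ``support`` and ``consensus_p``.  A TF-TF interaction
    is represented by two reciprocal directed edges.
    """

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def tf_nodes(self) -> list[str]:
        """Nodes acting as regulators (out-degree >= 1)."""
        return sorted(n for n, d in self.graph.out_degree() if d >= 1)

    @property
    def target_nodes(self) -> list[str]:
        """Nodes under regulation (in-degree >= 1); a node may be both."""
        return sorted(n for n, d in self.graph.in_degree() if d >= 1)

    def directed_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def undirected_pairs(self) -> set[Pair]:
        return {_pair(a, b) for a, b in self.graph.edges()}


def orient_and_trim(
    consensus: ConsensusNetwork | Mapping[Pair, ConsensusEdge],
    tf_ids: Iterable[str],
) -> RegulatoryNetwork:
    """Orient consensus pairs TF -> target and keep the giant component.

    TF-nonTF pairs become a single directed edge from the TF; TF-TF pairs
    become two reciprocal directed edges.  The largest weakly connected
    component is retained; among equal-sized components the one containing
    the lexicographically smallest node wins.
    """
    edges = consensus.edges if isinstance(consensus, ConsensusNetwork) else dict(consensus)
    if not edges:
        raise EmptyNetworkError("cannot orient an empty consensus network")
    tf_set = set(tf_ids)
    g = nx.DiGraph()
    for (a, b), stat in edges.items():
        attrs = {
            "mi": stat.mi if isinstance(stat, ConsensusEdge) else float(stat),
            "support": stat.support if isinstance(stat, ConsensusEdge) else 1,
            "consensus_p": stat.consensus_p if isinstance(stat, ConsensusEdge) else np.nan,
        }
        a_tf, b_tf = a in tf_set, b in tf_set
        if a_tf and b_tf:
            g.add_edge(a, b, **attrs)
            g.add_edge(b, a, **attrs)
        elif a_tf:
            g.add_edge(a, b, **attrs)
        elif b_tf:
            g.add_edge(b, a, **attrs)
        else:
            raise ValueError(f"edge {(a, b)} joins two non-TF genes")
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tf_set
    components = list(nx.weakly_connected_components(g))
    best_size = max(len(c) for c in components)
    giant = min((c for c in components if len(c) == best_size), key=min)
    return RegulatoryNetwork(nx.DiGraph(g.subgraph(giant)))
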