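"""Network comparison: overlap, lost-edge classes, gains, mutation test."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from grndiff.compare import (
    classify_lost_edges,
    edge_status,
    mutation_degree_association,
    overlap,
    rank_gains,
    round_half_away,
    summarize_comparison,
)
from grndiff.inference import RegulatoryNetwork
from grndiff.mi import calibrate_null


def net_from_edges(edges, tf_ids):
    g = nx.DiGraph()
    for a, b in edges:
        g.add_edge(a, b, mi=0.5, support=10, consensus_p=1e-9)
    for v in g.nodes:
        g.nodes[v]["is_tf"] = v in set(tf_ids)
    return RegulatoryNetwork(g)


@pytest.fixture(scope="module")
def calib():
    return calibrate_null(60, n_permutations=1000, seed=0)


class TestOverlapAndStatus:
    def test_identical_networks_full_overlap(self):
        net = net_from_edges([("T1", "a"), ("T1", "b")], ["T1"])
        ov = overlap(net, net)
        assert ov["shared_node_pct_of_tumor"] == 100.0
        assert ov["shared_edge_pct_of_tumor"] == 100.0

    def test_disjoint_networks_zero_overlap(self):
        a = net_from_edges([("T1", "a")], ["T1"])
        b = net_from_edges([("T2", "b")], ["T2"])
        ov = overlap(a, b)
        assert ov["shared_node_pct_of_tumor"] == 0.0
        assert ov["shared_edge_pct_of_tumor"] == 0.0

    def test_eight_of_ten_tumor_nodes_shared(self):
        normal = net_from_edges(
            [("T1", f"g{i}") for i in range(7)] + [("T1", "x1"), ("T1", "x2")], ["T1"]
        )
        tumor = net_from_edges(
            [("T1", f"g{i}") for i in range(7)] + [("T1", "y1"), ("T1", "y2")], ["T1"]
        )
        # tumor nodes: T1, g0..g6, y1, y2 -> 10, of which 8 in normal
        assert overlap(normal, tumor)["shared_node_pct_of_tumor"] == 80.0

    def test_status_partitions_union(self):
        normal = net_from_edges([("T1", "a"), ("T1", "b"), ("T2", "c")], ["T1", "T2"])
        tumor = net_from_edges([("T1", "a"), ("T2", "d")], ["T1", "T2"])
        status = edge_status(normal, tumor)
        lost = {e for e, s in status.items() if s == "lost"}
        conserved = {e for e, s in status.items() if s == "conserved"}
        gained = {e for e, s in status.items() if s == "gained"}
        assert len(lost) + len(conserved) == normal.n_edges
        assert len(gained) + len(conserved) == tumor.n_edges
        assert not (lost & gained) and not (lost & conserved) and not (gained & conserved)


def _expr(rows, n=60):
    return pd.DataFrame({f"s{i}": {g: v[i] for g, v in rows.items()} for i in range(n)})


def _profile(mean, rng, n=60, sd=0.3):
    return mean + sd * rng.standard_normal(n)


class TestClassifyLostEdges:
    def test_four_classes_from_stated_thresholds(self, calib, rng):
        normal = _expr(
            {
                "TFa": _profile(8, rng), "Ga": _profile(9, rng),
                "TFb": _profile(8, rng), "Gb": _profile(9, rng),
                "TFc": _profile(8, rng), "Gc": _profile(9, rng),
                "TFd": _profile(8, rng), "Gd": _profile(9, rng),
            }
        )
        tumor = _expr(
            {
                "TFa": _profile(2, rng), "Ga": _profile(2.5, rng),  # both silenced
                "TFb": _profile(7.5, rng), "Gb": _profile(3, rng),  # target only
                "TFc": _profile(3, rng), "Gc": _profile(9, rng),    # TF only
                "TFd": _profile(8, rng), "Gd": _profile(9, rng),    # neither
            }
        )
        lost = [("TFa", "Ga"), ("TFb", "Gb"), ("TFc", "Gc"), ("TFd", "Gd")]
        records = {
            (r.regulator_id, r.target_id): r
            for r in classify_lost_edges(lost, normal, tumor, calib, calib)
        }
        assert records[("TFa", "Ga")].edge_class == "A"
        assert records[("TFb", "Gb")].edge_class == "B"
        assert records[("TFc", "Gc")].edge_class == "C"
        assert records[("TFd", "Gd")].edge_class == "D"
        for r in records.values():
            assert r.delta_mi == pytest.approx(r.mi_tumor - r.mi_normal)

    def test_boundary_mean_exactly_four_not_silenced(self, calib):
        """Strict inequality: a tumor mean of exactly 4.0 is not silencing."""
        n = 60
        base = np.tile([-0.5, 0.5], n // 2)  # exact sample means
        normal = _expr({"TF": 8 + base, "G": 9 + base})
        tumor = _expr({"TF": 8 + base, "G": 4.0 + base})
        (rec,) = classify_lost_edges([("TF", "G")], normal, tumor, calib, calib)
        assert tumor.loc["G"].mean() == 4.0
        assert not rec.target_silenced
        assert rec.edge_class == "D"

    def test_boundary_log2fc_exactly_minus_one_not_silenced(self, calib):
        n = 60
        base = np.tile([-0.5, 0.5], n // 2)
        normal = _expr({"TF": 8 + base, "G": 4.5 + base})
        tumor = _expr({"TF": 8 + base, "G": 3.5 + base})  # mean 3.5 < 4, fc exactly -1
        (rec,) = classify_lost_edges([("TF", "G")], normal, tumor, calib, calib)
        assert rec.target_log2fc == -1.0
        assert not rec.target_silenced

    def test_missing_gene_named_in_error(self, calib, rng):
        normal = _expr({"TF": _profile(8, rng), "G": _profile(9, rng)})
        with pytest.raises(KeyError, match="GHOST"):
            classify_lost_edges([("TF", "GHOST")], normal, normal, calib, calib)


class TestRankGains:
    def test_snai2_like_out_degree_gain(self):
        normal_edges = [("SNAI2", "g0")] + [("T2", f"h{i}") for i in range(3)]
        tumor_edges = [("SNAI2", f"n{i}") for i in range(119)] + [("T2", "h0")]
        normal = net_from_edges(normal_edges, ["SNAI2", "T2"])
        tumor = net_from_edges(tumor_edges, ["SNAI2", "T2"])
        gains = rank_gains(normal, tumor)
        top = gains.tfs[0]
        assert top.node_id == "SNAI2"
        assert (top.degree_normal, top.degree_tumor) == (1, 119)
        assert top.gained == 118
        assert top.ratio == pytest.approx(119.0)

    def test_node_absent_from_normal_excluded(self):
        normal = net_from_edges([("T1", "a")], ["T1", "T9"])
        tumor = net_from_edges([("T1", "a"), ("T9", "b"), ("T9", "c")], ["T1", "T9"])
        gains = rank_gains(normal, tumor)
        assert all(r.node_id != "T9" for r in gains.tfs)

    def test_equal_degrees_empty(self):
        net = net_from_edges([("T1", "a"), ("T1", "b")], ["T1"])
        gains = rank_gains(net, net)
        assert gains.tfs == () and gains.targets == ()

    def test_summary_rounding(self):
        normal = net_from_edges([("T1", "a"), ("T2", "b")], ["T1", "T2"])
        tumor = net_from_edges(
            [("T1", "a"), ("T1", "c"), ("T1", "d"), ("T2", "b"), ("T2", "e")],
            ["T1", "T2"],
        )
        s = rank_gains(normal, tumor).summary()
        assert s["tf"]["n_nodes"] == 2
        assert s["tf"]["total_gained"] == 3
        assert s["tf"]["mean_gained"] == 1.5
        assert s["tf"]["median_gained"] == 1.5


class TestMutationAssociation:
    def test_null_p_large(self):
        """Identical in-degree distributions: p >= 0.5 typically, never tiny."""
        rng = np.random.default_rng(0)
        big = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            degs = rng.integers(1, 10, 200)
            edges = []
            for i, d in enumerate(degs):
                edges += [(f"T{j}", f"g{i}") for j in range(d)]
            net = net_from_edges(edges, [f"T{j}" for j in range(10)])
            freq = pd.Series(
                {f"g{i}": (10.0 if rng.random() < 0.5 else 1.0) for i in range(200)}
            )
            res = mutation_degree_association(net, freq)
            big += res["p_value"] >= 0.5
        assert big >= 25  # ~ uniform p-values: about half at p >= 0.5

    def test_planted_shift_detected(self):
        """Mutated group with +5 in-degree: p < 0.001 in >= 95% of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            edges, freq = [], {}
            for i in range(200):
                mutated = i < 100
                d = int(rng.integers(1, 6)) + (5 if mutated else 0)
                edges += [(f"T{j}", f"g{i}") for j in range(d)]
                freq[f"g{i}"] = 10.0 if mutated else 1.0
            net = net_from_edges(edges, [f"T{j}" for j in range(11)])
            res = mutation_degree_association(net, pd.Series(freq))
            hits += res["p_value"] < 0.001
        assert hits >= 48

    def test_threshold_strictly_greater(self):
        net = net_from_edges([("T1", "a"), ("T1", "b"), ("T2", "b")], ["T1", "T2"])
        freq = pd.Series({"a": 5.0, "b": 8.0})  # exactly 5% -> not mutated
        res = mutation_degree_association(net, freq, freq_threshold=5.0)
        assert res["n_mutated"] == 1 and res["n_not_mutated"] == 1

    def test_empty_group_flagged_untestable(self):
        net = net_from_edges([("T1", "a")], ["T1"])
        res = mutation_degree_association(net, pd.Series({"a": 1.0}))
        assert not res["testable"] and np.isnan(res["p_value"])


class TestSummarize:
    def test_printed_count_arithmetic(self):
        """61,226 -> 11,585 edges: 81% reduction, ratio 0.19."""
        assert round_half_away(100 * (1 - 11585 / 61226)) == 81
        assert round_half_away(11585 / 61226, 2) == 0.19

    def test_identical_networks_zero_reduction(self):
        net = net_from_edges([("T1", "a"), ("T1", "b"), ("T2", "a")], ["T1", "T2"])
        rep = summarize_comparison(net, net, [], rank_gains(net, net))
        assert all(v == 0 for v in rep.reductions_pct.values())
        assert all(v == 1.0 for v in rep.ratios.values())
        assert rep.overlap["shared_edge_pct_of_tumor"] == 100.0

    def test_class_percentages_recomputable(self, calib, rng):
        normal = _expr({"TF": _profile(8, rng), "G": _profile(9, rng), "H": _profile(9, rng)})
        tumor = _expr({"TF": _profile(8, rng), "G": _profile(9, rng), "H": _profile(2.4, rng)})
        net_n = net_from_edges([("TF", "G"), ("TF", "H")], ["TF"])
        net_t = net_from_edges([("TF", "G")], ["TF"])
        records = classify_lost_edges([("TF", "H")], normal, tumor, calib, calib)
        rep = summarize_comparison(net_n, net_t, records, rank_gains(net_n, net_t))
        total = sum(rep.lost_class_counts.values())
        assert total == 1
        for c in "ABCD":
            assert rep.lost_class_pct[c] == round_half_away(
                100 * rep.lost_class_counts[c] / total, 1
            )

    def test_round_half_away(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(24.44, 1) == 24.4
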