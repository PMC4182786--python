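"""DPI pruning, single-run inference, bootstrap consensus and orientation."""
import itertools

import numpy as np
import pandas as pd
import pytest

import grndiff as gd
from grndiff.inference import (
    ConsensusEdge,
    EmptyNetworkError,
    InferenceConfig,
    apply_dpi,
    bootstrap_consensus,
    infer_single_network,
    orient_and_trim,
    poisson_tail,
    _pair,
)
from grndiff.mi import calibrate_null


def brute_force_dpi(edges, tolerance=0.0):
    """Independent oracle: scan all node triples, mark, then delete."""
    nodes = sorted({n for e in edges for n in e})
    doomed = set()
    for a, b, c in itertools.combinations(nodes, 3):
        tri = [_pair(a, b), _pair(a, c), _pair(b, c)]
        if not all(t in edges for t in tri):
            continue
        for e in tri:
            others = [edges[t] for t in tri if t != e]
            if edges[e] * (1.0 + tolerance) <= min(others):
                doomed.add(e)
    return {e: m for e, m in edges.items() if e not in doomed}


def random_edge_set(seed, n_nodes=20, n_edges=60):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    while len(edges) < n_edges:
        a, b = rng.choice(n_nodes, 2, replace=False)
        edges[_pair(nodes[a], nodes[b])] = float(rng.uniform(0.05, 1.0))
    return edges


class TestDPI:
    def test_triangle_minimum_removed(self):
        edges = {("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.1}
        out = apply_dpi(edges, 0.0)
        assert set(out) == {("a", "b"), ("b", "c")}

    def test_two_edge_path_untouched(self):
        edges = {("a", "b"): 0.5, ("b", "c"): 0.01}
        assert apply_dpi(edges, 0.0) == edges

    def test_matches_brute_force_oracle(self):
        for seed in range(100):
            edges = random_edge_set(seed)
            assert apply_dpi(edges, 0.0) == brute_force_dpi(edges, 0.0)

    def test_large_tolerance_removes_nothing(self):
        for seed in range(10):
            edges = random_edge_set(seed)
            assert apply_dpi(edges, 1e9) == edges

    def test_tolerance_zero_removes_most(self):
        for seed in range(10):
            edges = random_edge_set(seed)
            assert set(apply_dpi(edges, 0.0)) <= set(apply_dpi(edges, 0.5))

    def test_removed_edges_are_a_triangle_minimum(self):
        """Every removed edge is the (weak) minimum of some triangle, so a
        triangle's strictly strongest edge is never marked through it."""
        for seed in range(20):
            edges = random_edge_set(seed, n_nodes=10, n_edges=25)
            removed = set(edges) - set(apply_dpi(edges, 0.0))
            nodes = sorted({n for e in edges for n in e})
            for e in removed:
                witnesses = []
                for a, b, c in itertools.combinations(nodes, 3):
                    tri = [_pair(a, b), _pair(a, c), _pair(b, c)]
                    if e in tri and all(t in edges for t in tri):
                        others = [edges[t] for t in tri if t != e]
                        witnesses.append(edges[e] <= min(others))
                assert any(witnesses)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apply_dpi({("a", "b"): 0.1}, -0.5)


@pytest.fixture(scope="module")
def small_calibration():
    return calibrate_null(80, n_permutations=2000, seed=5)


def _expr_from_profiles(profiles: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {f"s{i}": {g: v[i] for g, v in profiles.items()} for i in range(len(next(iter(profiles.values()))))}
    )


class TestSingleNetwork:
    def test_candidate_pairs_restricted_to_tf_adjacent(self, small_calibration):
        """Two strongly coupled non-TF genes can never form an edge."""
        rng = np.random.default_rng(0)
        tf = rng.standard_normal(80)
        a = tf + 0.01 * rng.standard_normal(80)  # driven by TF
        b = a + 0.01 * rng.standard_normal(80)  # tightly coupled to a
        expr = _expr_from_profiles({"TF1": tf, "A": a, "B": b})
        edges = infer_single_network(expr, ["TF1"], small_calibration, InferenceConfig())
        assert all("TF1" in e for e in edges)

    def test_planted_star_recovered(self, small_calibration):
        net = gd.generate_grn(1, 10, 10, seed=3)
        expr = gd.simulate_expression(net, 100, noise_sd=0.3, seed=4)
        edges = infer_single_network(
            expr.condition("normal"), ["TF000"], small_calibration, InferenceConfig()
        )
        recovered = {e for e in edges}
        for _, tgt, _ in net.edges:
            assert _pair("TF000", tgt) in recovered

    def test_chain_indirect_edge_removed_by_dpi(self, small_calibration):
        """TF1 -> TF2 -> gene: the 2-hop TF1-gene association is pruned."""
        rng = np.random.default_rng(1)
        tf1 = rng.standard_normal(80)
        tf2 = tf1 + 0.25 * rng.standard_normal(80)
        gene = tf2 + 0.25 * rng.standard_normal(80)
        expr = _expr_from_profiles({"TF1": tf1, "TF2": tf2, "G": gene})
        cfg = InferenceConfig()
        edges = infer_single_network(expr, ["TF1", "TF2"], small_calibration, cfg)
        assert _pair("TF1", "TF2") in edges
        assert _pair("TF2", "G") in edges
        assert _pair("TF1", "G") not in edges

    def test_no_tf_in_matrix_raises(self, small_calibration):
        expr = _expr_from_profiles({"A": np.random.default_rng(0).standard_normal(80)})
        with pytest.raises(ValueError):
            infer_single_network(expr, ["TFX"], small_calibration, InferenceConfig())


class TestConsensus:
    def test_poisson_tail_equals_series_oracle(self):
        """Direct pmf summation for k up to 50, lambda up to 10."""
        import math

        for lam in (0.5, 1.0, 3.0, 7.5, 10.0):
            for k in (1, 2, 5, 10, 25, 50):
                series = 1.0 - sum(
                    math.exp(-lam) * lam**j / math.factorial(j) for j in range(k)
                )
                assert poisson_tail(k, lam) == pytest.approx(series, abs=1e-12)

    def test_always_detected_edge_retained_when_lambda_small(
        self, small_calibration, monkeypatch
    ):
        """An edge present in all B replicates survives when lam << B."""
        import grndiff.inference as inf

        calls = {"i": 0}

        def scripted(values, gene_ids, tf_positions, mi_min, tol, h):
            # one ever-present strong edge plus a rotating singleton, so the
            # chance rate lam stays near 2 while the real edge reaches B
            i = calls["i"]
            calls["i"] += 1
            return {("TF000", "G0000"): 0.5, ("TF000", f"junk{i}"): 0.3}

        monkeypatch.setattr(inf, "_infer_from_values", scripted)
        expr = pd.DataFrame(
            np.random.default_rng(0).standard_normal((3, 20)),
            index=["TF000", "G0000", "G0001"],
        )
        cfg = InferenceConfig(n_bootstrap=30, seed=11)
        cons = bootstrap_consensus(expr, ["TF000"], small_calibration, cfg)
        assert cons.lam < 5
        assert cons.edges[("TF000", "G0000")].support == 30
        assert all("junk" not in a and "junk" not in b for a, b in cons.edges)

    def test_consensus_deterministic_for_fixed_seed(self, small_calibration):
        net = gd.generate_grn(2, 8, 5, seed=9)
        expr = gd.simulate_expression(net, 80, noise_sd=0.3, seed=2).condition("normal")
        cfg = InferenceConfig(n_bootstrap=20, seed=11)
        a = bootstrap_consensus(expr, ["TF000", "TF001"], small_calibration, cfg)
        b = bootstrap_consensus(expr, ["TF000", "TF001"], small_calibration, cfg)
        assert a.edges == b.edges and a.lam == b.lam

    def test_b1_degenerates_to_single_run(self, small_calibration):
        net = gd.generate_grn(1, 5, 5, seed=1)
        expr = gd.simulate_expression(net, 80, noise_sd=0.3, seed=3).condition("normal")
        cfg = InferenceConfig(n_bootstrap=1, min_support_fraction=0.0, seed=4)
        cons = bootstrap_consensus(expr, ["TF000"], small_calibration, cfg)
        # all support 1 and lam 1: the Bonferroni Poisson test may keep none
        assert cons.n_bootstrap == 1
        assert all(e.support == 1 for e in cons.edges.values())

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            InferenceConfig(n_bootstrap=0)
        with pytest.raises(ValueError):
            InferenceConfig(p_threshold=2.0)
        with pytest.raises(ValueError):
            InferenceConfig(dpi_tolerance=-1.0)


def _consensus(pairs):
    return {p: ConsensusEdge(mi=m, support=10, consensus_p=1e-9) for p, m in pairs.items()}


class TestOrientAndTrim:
    def test_giant_component_kept(self):
        pairs = _consensus(
            {
                ("T1", "a"): 0.5,
                ("T1", "b"): 0.5,
                ("T2", "b"): 0.4,
                ("T2", "c"): 0.4,  # 5-node component: T1,T2,a,b,c
                ("T3", "x"): 0.9,
                ("T3", "y"): 0.9,  # 3-node component
            }
        )
        net = orient_and_trim(pairs, ["T1", "T2", "T3"])
        assert set(net.graph) == {"T1", "T2", "a", "b", "c"}

    def test_tf_tf_pair_reciprocal(self):
        pairs = _consensus({("T1", "T2"): 0.6, ("T1", "a"): 0.5})
        net = orient_and_trim(pairs, ["T1", "T2"])
        assert net.graph.has_edge("T1", "T2") and net.graph.has_edge("T2", "T1")
        assert net.n_edges == 3
        from grndiff.topology import multi_edge_pairs

        assert multi_edge_pairs(net.graph) == 1

    def test_equal_size_tie_break_lexicographic(self):
        pairs = _consensus({("T1", "b"): 0.5, ("T2", "z"): 0.9})
        net = orient_and_trim(pairs, ["T1", "T2"])
        assert set(net.graph) == {"T1", "b"}

    def test_direction_is_tf_to_target(self):
        pairs = _consensus({("a", "T1"): 0.5})
        net = orient_and_trim(pairs, ["T1"])
        assert list(net.graph.edges()) == [("T1", "a")]
        assert net.tf_nodes == ["T1"] and net.target_nodes == ["a"]

    def test_empty_raises(self):
        with pytest.raises(EmptyNetworkError):
            orient_and_trim({}, ["T1"])
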