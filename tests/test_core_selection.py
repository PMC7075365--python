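import numpy as np
import pytest

from coreset_gbs.core_selection import (
    CoreTrace,
    CoreRemoval,
    choose_core_size,
    detect_synonyms,
    evaluate_core,
    max_length_subtree,
    sphericity_index,
)
from coreset_gbs.io_formats import SquareMatrix
from coreset_gbs.nj_tree import neighbor_joining, sqrt_transform
from coreset_gbs.popgen_stats import ibs_distance

from conftest import make_geno
from test_nj_tree import random_additive_tree


def panel_with_duplicates(seed=0, n=10, m=80):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    d[1] = d[0]  # s2 is an exact duplicate of s1
    return make_geno(d)


def tree_of(geno):
    return neighbor_joining(sqrt_transform(ibs_distance(geno)))


class TestMaxLengthSubtree:
    def test_target_equals_n_is_identity(self):
        rng = np.random.default_rng(1)
        tree, _ = random_additive_tree(6, rng)
        core, trace = max_length_subtree(tree, 6)
        assert core.retained == tree.leaf_labels
        assert trace.removals == []

    def test_duplicate_removed_first_with_zero_edge(self):
        geno = panel_with_duplicates()
        tree = tree_of(geno)
        core, trace = max_length_subtree(tree, geno.n_samples - 1)
        first = trace.removals[0]
        assert first.removed == "s2"  # lexicographically later twin goes
        assert first.removed_edge_value == pytest.approx(0.0, abs=1e-12)
        assert first.nearest_retained == "s1"

    def test_must_keep_protects_redundant_accession(self):
        geno = panel_with_duplicates()
        tree = tree_of(geno)
        core, trace = max_length_subtree(tree, geno.n_samples - 1, must_keep={"s2"})
        assert trace.removals[0].removed == "s1"
        assert "s2" in core.retained

    def test_must_keep_never_removed_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            tree, _ = random_additive_tree(8, rng)
            keep = set(rng.choice(tree.leaf_labels, size=3, replace=False))
            core, trace = max_length_subtree(tree, 3, must_keep=keep)
            assert keep <= set(core.retained)
            assert all(r.removed not in keep for r in trace.removals)

    def test_unknown_must_keep_errors(self):
        tree, _ = random_additive_tree(5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown"):
            max_length_subtree(tree, 4, must_keep={"ghost"})

    def test_target_too_large_errors(self):
        tree, _ = random_additive_tree(5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="target_size"):
            max_length_subtree(tree, 6)

    def test_trace_invariants(self):
        rng = np.random.default_rng(3)
        tree, dist = random_additive_tree(9, rng)
        core, trace = max_length_subtree(tree, 3, distances=dist)
        sizes = [r.retained_size for r in trace.removals]
        assert sizes == list(range(8, 2, -1))
        lengths = [trace.initial_length] + [r.retained_length for r in trace.removals]
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_nested_cores(self):
        rng = np.random.default_rng(5)
        tree, _ = random_additive_tree(10, rng)
        core_small, trace = max_length_subtree(tree, 4)
        ids = tree.leaf_labels
        for size in range(4, 10):
            inner = set(trace.retained_at(size, ids))
            outer = set(trace.retained_at(size + 1, ids))
            assert inner <= outer

    def test_greedy_beats_random_subsets(self):
        """Retained tree length of the greedy core >= random subsets >=95% of trials."""
        rng = np.random.default_rng(11)
        wins = 0
        trials = 100
        tree, _ = random_additive_tree(12, rng)
        k = 6
        core, _ = max_length_subtree(tree, k)

        def retained_length(subset):
            t = tree.copy()
            for lab in tree.leaf_labels:
                if lab not in subset:
                    t.remove_leaf(lab)
            return t.total_length()

        greedy_len = retained_length(set(core.retained))
        for _ in range(trials):
            subset = set(rng.choice(tree.leaf_labels, size=k, replace=False))
            if greedy_len >= retained_length(subset) - 1e-9:
                wins += 1
        assert wins >= 95


class TestSphericityIndex:
    def test_all_equal_distances(self):
        m = SquareMatrix(["a", "b", "c"], (np.ones((3, 3)) - np.eye(3)) * 0.4)
        assert sphericity_index(m, ["a", "b", "c"]) == 1.0

    def test_single_pair(self):
        m = SquareMatrix(["a", "b"], [[0, 0.7], [0.7, 0]])
        assert sphericity_index(m, ["a", "b"]) == 1.0

    def test_mean_over_max(self):
        m = SquareMatrix(
            ["a", "b", "c"], [[0, 1, 1], [1, 0, 4], [1, 4, 0]]
        )
        assert sphericity_index(m, ["a", "b", "c"]) == pytest.approx(0.5)

    def test_identical_points_defined_one(self):
        m = SquareMatrix(["a", "b"], [[0, 0], [0, 0]])
        assert sphericity_index(m, ["a", "b"]) == 1.0


def trace_from_curve(points):
    """Build a minimal CoreTrace whose sphericity curve equals ``points``."""
    removals = [
        CoreRemoval(step=i + 1, removed=f"r{i}", removed_edge_value=0.0,
                    nearest_retained="x", retained_length=1.0,
                    sphericity=val, retained_size=size)
        for i, (size, val) in enumerate(sorted(points, key=lambda p: -p[0]))
    ]
    return CoreTrace(initial_length=1.0, initial_size=removals[0].retained_size + 1,
                     removals=removals)


class TestChooseCoreSize:
    def test_linear_curve_flags_no_knee(self):
        trace = trace_from_curve([(10, 1.0), (9, 0.9), (8, 0.8), (7, 0.7)])
        res = choose_core_size(trace, "sphericity")
        assert res.no_knee
        assert res.size == 10

    def test_l_shape_corner(self):
        pts = [(s, 1.0) for s in range(20, 10, -1)] + [
            (10, 1.0), (9, 0.5), (8, 0.25), (7, 0.1), (6, 0.0)
        ]
        res = choose_core_size(trace_from_curve(pts), "sphericity")
        assert res.size == 10

    def test_hand_computed_knee(self):
        # chord rule by hand: normalized deviations are 0.2333/0.45/0.4167 at
        # sizes 9/8/7, so the knee sits at retained size 8
        trace = trace_from_curve(
            [(10, 1.0), (9, 0.99), (8, 0.97), (7, 0.80), (6, 0.40)]
        )
        res = choose_core_size(trace, "sphericity")
        assert res.size == 8
        assert not res.no_knee

    def test_too_few_points_errors(self):
        trace = trace_from_curve([(5, 1.0), (4, 0.5)])
        with pytest.raises(ValueError, match="3"):
            choose_core_size(trace)

    def test_retained_length_curve(self):
        rng = np.random.default_rng(2)
        tree, dist = random_additive_tree(10, rng)
        _, trace = max_length_subtree(tree, 3, distances=dist)
        res = choose_core_size(trace, "retained_length")
        assert 3 <= res.size <= 9


class TestDetectSynonyms:
    def test_duplicates_reported(self):
        geno = panel_with_duplicates()
        tree = tree_of(geno)
        _, trace = max_length_subtree(tree, geno.n_samples - 2)
        pairs = detect_synonyms(trace)
        assert ("s2", "s1") in pairs

    def test_empty_when_above_threshold(self):
        rng = np.random.default_rng(1)
        tree, _ = random_additive_tree(8, rng)  # edges >= 0.1 >> 0.0008
        _, trace = max_length_subtree(tree, 4)
        assert detect_synonyms(trace) == []

    def test_default_threshold_value(self):
        from coreset_gbs.core_selection import SYNONYM_THRESHOLD

        assert SYNONYM_THRESHOLD == 0.0008


class TestEvaluateCore:
    def test_full_panel_identity(self, small_panel):
        geno, _ = small_panel
        ev = evaluate_core(geno, list(geno.sample_ids))
        assert ev.retention_pct == pytest.approx(100.0)
        assert ev.max_allele_freq_delta == pytest.approx(0.0, abs=1e-12)
        assert ev.ho_ratio == pytest.approx(1.0)

    def test_lost_site_counted(self):
        # minor allele of site 0 carried only by s1
        geno = make_geno([[1, 1], [0, 2], [0, 1], [0, 0]])
        ev = evaluate_core(geno, ["s2", "s3", "s4"])
        assert ev.seg_sites_whole == 2
        assert ev.retention_pct == pytest.approx(50.0)

    def test_empty_core_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ValueError, match="empty"):
            evaluate_core(geno, [])

    def test_unknown_id_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ValueError, match="not in panel"):
            evaluate_core(geno, ["nope"])


class TestRedundantFirstOrdering:
    def test_removed_edge_values_trend_upward(self):
        # clustered toy: tight cherries pruned before spread-out leaves
        rng = np.random.default_rng(13)
        corr = []
        for _ in range(5):
            tree, _ = random_additive_tree(12, rng)
            _, trace = max_length_subtree(tree, 3)
            vals = [r.removed_edge_value for r in trace.removals]
            steps = np.arange(len(vals))
            if np.std(vals) > 0:
                corr.append(np.corrcoef(steps, vals)[0, 1])
        assert np.mean(corr) > 0
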