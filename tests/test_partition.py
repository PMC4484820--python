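"""Cut-point search and tree construction against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import roctree as rt
from roctree.partition import MIN_BRANCH

from .oracles import (brute_force_best_cutpoint, enumerate_cutpoints_oracle,
                      kappa_oracle)
from .conftest import make_frame, random_frame


class TestKappa:
    @pytest.mark.parametrize("table,expected", [
        (((10, 0), (0, 10)), 1.0),          # perfect agreement
        (((5, 5), (5, 5)), 0.0),            # independence
        (((0, 10), (10, 0)), -1.0),         # perfect disagreement
        (((10, 10), (0, 0)), 0.0),          # degenerate margin sentinel
    ])
    def test_canonical_tables(self, table, expected):
        assert rt.kappa_2x2(table) == pytest.approx(expected)

    def test_matches_formula_oracle(self):
        assert rt.kappa_2x2(((18, 2), (17, 15))) == pytest.approx(
            kappa_oracle(((18, 2), (17, 15))), abs=1e-12)

    def test_matches_sklearn_on_label_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            pred = [1] * (a + b) + [0] * (c + d)
            obs = [1] * a + [0] * b + [1] * c + [0] * d
            expected = sklearn_metrics.cohen_kappa_score(pred, obs)
            if np.isnan(expected):
                expected = 0.0
            assert rt.kappa_2x2(((a, b), (c, d))) == pytest.approx(
                expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [((1, -1), (0, 2)), ((0.5, 1), (1, 1))])
    def test_rejects_invalid_counts(self, bad):
        with pytest.raises(ValueError):
            rt.kappa_2x2(bad)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_swap_symmetry(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        k = rt.kappa_2x2(((a, b), (c, d)))
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        # swapping branches *and* outcome labels leaves agreement intact
        assert rt.kappa_2x2(((d, c), (b, a))) == pytest.approx(k, abs=1e-12)


class TestEnumerate:
    def test_threshold_set_drops_empty_branch(self):
        df = make_frame({"x": [1.0, 2.0, 2.0, 3.0]}, [True, False, False, True])
        cps = rt.enumerate_cutpoints(df, "x")
        assert [c.threshold for c in cps] == [2.0, 3.0]

    def test_constant_feature_yields_nothing(self):
        df = make_frame({"x": [5.0] * 4}, [True, False, False, True])
        assert rt.enumerate_cutpoints(df, "x") == []

    def test_agrees_with_bruteforce_on_toy_subsample(self):
        rng = np.random.default_rng(3)
        df = random_frame(rng, 8, 1)
        cps = rt.enumerate_cutpoints(df, "f0")
        expected = enumerate_cutpoints_oracle(df, "f0")
        assert len(cps) == len(expected)
        for cp, (v, table) in zip(cps, expected):
            assert cp.threshold == v
            # package table is direction-ordered; compare the ge-side counts
            ge_row = cp.table[0] if cp.direction == "ge" else cp.table[1]
            assert ge_row == table[0]
            assert cp.kappa == pytest.approx(
                kappa_oracle(cp.table), abs=1e-12)

    def test_candidate_table_sums_to_subsample(self):
        rng = np.random.default_rng(4)
        df = random_frame(rng, 20, 1)
        for cp in rt.enumerate_cutpoints(df, "f0"):
            assert sum(sum(r) for r in cp.table) == len(df)


class TestBestCutpoint:
    def test_recovers_planted_single_split(self):
        x = [1.0, 1.5, 2.0, 2.5, 5.0, 5.5, 6.0, 6.5]
        remitted = [False, False, False, False, True, True, True, True]
        df = make_frame({"noise": [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0],
                         "x": x}, remitted)
        cp = rt.best_cutpoint(df, ["noise", "x"], alpha=0.05)
        assert cp.feature == "x"
        assert cp.threshold == 5.0
        assert cp.direction == "lt"  # low x side is all non-remitters
        assert cp.kappa == pytest.approx(1.0)

    def test_single_outcome_class_returns_none(self):
        df = make_frame({"x": [1.0, 2.0, 3.0, 4.0]}, [True] * 4)
        assert rt.best_cutpoint(df, ["x"]) is None

    def test_empty_feature_list_is_an_error(self):
        df = make_frame({"x": [1.0, 2.0]}, [True, False])
        with pytest.raises(ValueError):
            rt.best_cutpoint(df, [])

    def test_agrees_with_bruteforce_on_toy_table(self):
        rng = np.random.default_rng(7)
        df = random_frame(rng, 12, 2)
        cp = rt.best_cutpoint(df, ["f0", "f1"], alpha=0.5)
        expected = brute_force_best_cutpoint(df, ["f0", "f1"], alpha=0.5)
        if expected is None:
            assert cp is None
        else:
            feat, v, direction, k, p = expected
            assert (cp.feature, cp.threshold, cp.direction) == (feat, v, direction)
            assert cp.kappa == pytest.approx(k, abs=1e-12)
            assert cp.p_value == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_random_instances(self, seed):
        """Exhaustive-search equivalence on small random cohorts."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(6, 31))
        nf = int(rng.integers(1, 6))
        alpha = float(rng.choice([0.01, 0.05, 0.2]))
        df = random_frame(rng, n, nf)
        feats = [f"f{j}" for j in range(nf)]
        cp = rt.best_cutpoint(df, feats, alpha=alpha)
        expected = brute_force_best_cutpoint(df, feats, alpha=alpha)
        if expected is None:
            assert cp is None
        else:
            assert (cp.feature, cp.threshold, cp.direction) == expected[:3]
            assert cp.kappa == pytest.approx(expected[3], abs=1e-12)


def _planted_depth2_frame(seed=0, n=90):
    """Noise-free depth-2 structure: labels fully determined by two cuts."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 10, n)
    b = rng.uniform(0, 10, n)
    noise = rng.uniform(0, 10, n)
    remitted = [(ai >= 6.0) or (ai < 6.0 and bi < 3.0) for ai, bi in zip(a, b)]
    return make_frame({"a": a, "b": b, "noise": noise}, remitted)


class TestBuildTree:
    def test_tiny_alpha_gives_single_leaf(self):
        rng = np.random.default_rng(5)
        df = random_frame(rng, 20, 3)
        tree = rt.build_tree(df, ["f0", "f1", "f2"], alpha=1e-12)
        assert tree.root.is_leaf

    def test_recovers_planted_depth2_tree(self):
        df = _planted_depth2_frame()
        tree = rt.build_tree(df, ["noise", "a", "b"], alpha=0.01)
        root = tree.root
        assert root.cut.feature == "a"
        a = df["a"].to_numpy()
        assert a[a < 6.0].max() < root.cut.threshold <= a[a >= 6.0].min()
        inner = root.children["lt"]
        assert inner.cut.feature == "b"
        b = df["b"].to_numpy()[a < root.cut.threshold]
        assert b[b < 3.0].max() < inner.cut.threshold <= b[b >= 3.0].min()
        # the recovered partition routes every subject to a pure leaf
        for node in tree.nodes():
            if node.is_leaf:
                assert node.n_remit == 0 or node.n_nonremit == 0

    def test_determinism(self, test_cohort):
        feats = list(rt.jhu_tracts())
        t1 = rt.build_tree(test_cohort, feats)
        t2 = rt.build_tree(test_cohort, feats)
        assert t1.to_dict() == t2.to_dict()

    def test_partition_conservation_and_stopping(self, test_cohort):
        tree = rt.build_tree(test_cohort, list(rt.aal_regions()))
        for node in tree.nodes():
            if not node.is_leaf:
                ge, lt = node.children["ge"], node.children["lt"]
                assert ge.n + lt.n + node.n_unrouted == node.n
                assert node.cut.p_value < tree.alpha
                assert ge.n < node.n and lt.n < node.n
                assert ge.n >= MIN_BRANCH and lt.n >= MIN_BRANCH
            assert node.n_remit >= 0 and node.n_nonremit >= 0
            if node.n:
                assert node.p_remission == pytest.approx(
                    node.n_remit / node.n)

    def test_empty_cohort_is_an_error(self):
        df = make_frame({"x": []}, [])
        with pytest.raises(ValueError):
            rt.build_tree(df, ["x"])

    def test_json_round_trip(self, test_cohort, tmp_path):
        tree = rt.build_tree(test_cohort, list(rt.jhu_tracts()))
        path = tmp_path / "tree.json"
        tree.save(path)
        assert rt.DecisionTree.load(path).to_dict() == tree.to_dict()


class TestParameterRecovery:
    def test_root_feature_recovered_across_simulations(self):
        """Planted depth-2 tree, n=150, leaf rates 0.9/0.1: the root split
        feature should be found in nearly every simulated cohort."""
        spec = rt.CohortSpec(
            name="sim", n=150, remission_rate=0.5,
            trees={"volumes": rt.PlantedTreeSpec(
                splits=(rt.PlantedSplit("Frontal_Mid_L", 14.82, "lt",
                                        rt.PlantedLeaf(75, 0.9)),),
                final_leaf=rt.PlantedLeaf(75, 0.1))})
        fm = rt.FeatureModel(overrides={"Frontal_Mid_L": (14.82, 2.0)})
        hits = 0
        n_runs = 30
        for s in range(n_runs):
            cfg = rt.CohortConfig(cohorts=(spec,), feature_model=fm)
            df = rt.simulate_cohort(cfg, seed=s)
            tree = rt.build_tree(df, list(rt.aal_regions()))
            cut = tree.root.cut
            if cut is not None and cut.feature == "Frontal_Mid_L":
                # label noise can shift the optimum by a boundary subject,
                # so require proximity rather than the exact flanking gap
                assert abs(cut.threshold - 14.82) < 0.5
                hits += 1
        assert hits >= round(0.95 * n_runs)
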