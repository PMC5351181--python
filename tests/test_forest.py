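import itertools

import numpy as np
import pytest

from imbforest.datasets import make_informative_gaussian
from imbforest.forest import (RandomForest, best_split,
                              bootstrap_distinct_fraction, gini, gini_split,
                              train_forest)


def exhaustive_best_split(X, y, features, min_leaf=1):
    """Brute force over every (feature, midpoint) pair using the plain
    weighted-Gini definition in exact rational arithmetic (score ties are
    frequent on tiny nodes, so the oracle must be exact to share the
    lowest-feature/lowest-threshold tie rule)."""
    from fractions import Fraction
    best = None
    n = len(y)
    for f in sorted(features):
        vals = np.sort(np.unique(X[:, f]))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue

            def frac_gini(lbls):
                _, cnt = np.unique(lbls, return_counts=True)
                return 1 - sum(Fraction(int(c), len(lbls)) ** 2 for c in cnt)

            score = (len(left) * frac_gini(left)
                     + len(right) * frac_gini(right)) / n
            if best is None or score < best[2]:
                best = (f, thr, score)
    return None if best is None else (best[0], best[1], float(best[2]))


class TestGini:
    @pytest.mark.parametrize("labels,expected", [
        ([1, 1, 1], 0.0),
        ([1, 1, 0, 0], 0.5),
        ([0, 1, 2], 2.0 / 3.0),
    ])
    def test_values(self, labels, expected):
        assert gini(labels) == pytest.approx(expected, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini([])

    @pytest.mark.parametrize("labels,partition,expected", [
        ([1, 1, 0, 0], [[1, 1], [0, 0]], 0.0),
        ([1, 1, 0, 0], [[1, 1, 0, 0]], 0.5),
        ([1, 1, 1, 0, 0, 0], [[1, 1, 0], [1, 0, 0]], 4.0 / 9.0),
    ])
    def test_weighted_split(self, labels, partition, expected):
        assert gini_split(labels, partition) == pytest.approx(expected,
                                                              abs=1e-15)

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            gini_split([1, 0, 0], [[1], [1]])


class TestBestSplit:
    def test_separable_midpoint(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, score = best_split(X, y, [0])
        assert (f, thr) == (0, 5.0)
        assert score == pytest.approx(0.0)

    def test_constant_feature_gives_none(self):
        X = np.full((6, 1), 3.0)
        y = np.array([0, 1, 0, 1, 0, 1])
        assert best_split(X, y, [0]) is None

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.RandomState(0)
        for _ in range(200):
            X = rng.uniform(size=(8, 3))
            y = rng.randint(0, 2, size=8)
            if len(np.unique(y)) < 2:
                continue
            ours = best_split(X, y, [0, 1, 2])
            ref = exhaustive_best_split(X, y, [0, 1, 2])
            assert (ours is None) == (ref is None)
            if ours is not None:
                assert ours[0] == ref[0]
                assert ours[1] == pytest.approx(ref[1], abs=1e-12)
                assert ours[2] == pytest.approx(ref[2], abs=1e-12)

    def test_jitted_split_matches_reference(self):
        # the numba node-split kernel must reproduce the pure-Python rule
        from imbforest.forest import _node_best_split
        rng = np.random.RandomState(1)
        for _ in range(100):
            X = rng.uniform(size=(10, 4))
            y = rng.randint(0, 3, size=10).astype(np.int64)
            if len(np.unique(y)) < 2:
                continue
            feats = np.array([0, 1, 2, 3], dtype=np.int64)
            f, thr, score = _node_best_split(
                X, y, np.arange(10, dtype=np.int64), 0, 10, feats, 3, 1)
            ref = best_split(X, y, [0, 1, 2, 3])
            if ref is None:
                assert f == -1
            else:
                assert f == ref[0]
                assert thr == pytest.approx(ref[1], abs=1e-12)
                assert score == pytest.approx(ref[2], abs=1e-12)


class TestForest:
    def test_single_tree_fits_bootstrap_perfectly(self):
        rng = np.random.RandomState(2)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        rf = RandomForest(n_trees=1, kappa=3, max_depth=50, random_state=0)
        rf.fit(X, y)
        boot = rf.bootstrap_indices_[0]
        pred = rf.predict(X[boot])
        assert np.array_equal(pred, y[boot])

    def test_zero_trees_rejected(self):
        with pytest.raises(ValueError):
            RandomForest(n_trees=0).fit(np.zeros((4, 2)), [0, 1, 0, 1])

    def test_kappa_exceeding_features_rejected(self):
        with pytest.raises(ValueError):
            RandomForest(kappa=5).fit(np.zeros((4, 2)) +
                                      np.arange(4)[:, None], [0, 1, 0, 1])

    def test_seed_determinism(self, gaussian_ds):
        probe = gaussian_ds.features[:40]
        p1 = RandomForest(n_trees=30, random_state=9).fit(
            gaussian_ds.features, gaussian_ds.labels).predict_proba(probe)
        p2 = RandomForest(n_trees=30, random_state=9).fit(
            gaussian_ds.features, gaussian_ds.labels).predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_vote_fractions_sum_to_one(self, gaussian_ds):
        rf = RandomForest(n_trees=17, random_state=1).fit(
            gaussian_ds.features, gaussian_ds.labels)
        proba = rf.predict_proba(gaussian_ds.features[:25])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_tie_goes_to_smallest_label(self):
        # two trees, forced disagreement on a point between two pure blobs
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        y = np.array(["a", "a", "b", "b"])
        for seed in range(30):
            rf = RandomForest(n_trees=2, kappa=1, random_state=seed).fit(X, y)
            proba = rf.predict_proba([[5.0]])
            if proba[0, 0] == 0.5:
                assert rf.predict([[5.0]])[0] == "a"
                break
        else:
            pytest.skip("no split vote produced in 30 seeds")

    def test_oob_error_near_half_for_random_labels(self):
        errs = []
        for seed in range(10):
            rng = np.random.RandomState(seed)
            X = rng.normal(size=(200, 4))
            y = rng.randint(0, 2, size=200)
            rf = RandomForest(n_trees=40, random_state=seed).fit(X, y)
            errs.append(rf.oob_error_)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.05)

    def test_oob_error_small_for_separated_blobs(self):
        rng = np.random.RandomState(3)
        X = np.vstack([rng.normal(0, 0.5, (100, 3)),
                       rng.normal(10, 0.5, (100, 3))])
        y = np.array([0] * 100 + [1] * 100)
        rf = RandomForest(n_trees=50, random_state=0).fit(X, y)
        assert rf.oob_error_ < 0.05
        assert rf.oob_error_aggregate_ < 0.05

    def test_more_trees_do_not_hurt_aggregate_oob(self, gaussian_ds):
        deltas = []
        for seed in range(20):
            small = RandomForest(n_trees=10, random_state=seed).fit(
                gaussian_ds.features, gaussian_ds.labels)
            big = RandomForest(n_trees=200, random_state=seed).fit(
                gaussian_ds.features, gaussian_ds.labels)
            deltas.append(big.oob_error_aggregate_ - small.oob_error_aggregate_)
        assert np.mean(deltas) <= 0.02

    def test_margin_extremes_and_algebra(self):
        rng = np.random.RandomState(4)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)),
                       rng.normal(9, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        rf = RandomForest(n_trees=25, random_state=0).fit(X, y)
        assert rf.vote_margin(X, y) == pytest.approx(1.0)
        # all trees wrong: flip the labels -> margin -1
        assert rf.vote_margin(X, 1 - y) == pytest.approx(-1.0)
        # fraction v of trees correct on every sample -> margin 2v - 1
        proba = rf.predict_proba(X)
        v = proba[np.arange(len(y)), np.searchsorted(rf.classes_, y)]
        assert rf.vote_margin(X, y) == pytest.approx(np.mean(2 * v - 1))

    def test_predict_invariant_to_probe_order(self, gaussian_ds):
        rf = RandomForest(n_trees=20, random_state=5).fit(
            gaussian_ds.features, gaussian_ds.labels)
        probe = gaussian_ds.features[:30]
        perm = np.random.RandomState(0).permutation(30)
        np.testing.assert_array_equal(rf.predict(probe)[perm],
                                      rf.predict(probe[perm]))

    def test_train_forest_wrapper(self, gaussian_ds):
        rf = train_forest(gaussian_ds, n_trees=10, seed=3)
        assert rf.oob_error_ < 0.5

    def test_forest_dump_is_parseable_text(self, tmp_path, gaussian_ds):
        from imbforest.forest import dump_forest
        rf = RandomForest(n_trees=2, random_state=0).fit(
            gaussian_ds.features, gaussian_ds.labels)
        p = tmp_path / "forest.tsv"
        dump_forest(rf, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0].startswith("tree\tnode")
        assert len(lines) > 3


class TestBootstrap:
    def test_distinct_fraction_converges(self):
        frac = bootstrap_distinct_fraction(1000, replicates=200, seed=0)
        assert frac == pytest.approx(1 - (1 - 1 / 1000) ** 1000, abs=0.01)
        assert frac == pytest.approx(0.63, abs=0.01)

    def test_forest_bootstraps_have_expected_coverage(self, gaussian_ds):
        rf = RandomForest(n_trees=50, random_state=7).fit(
            gaussian_ds.features, gaussian_ds.labels)
        n = gaussian_ds.n
        fracs = [len(np.unique(rf.bootstrap_indices_[t])) / n
                 for t in range(50)]
        assert np.mean(fracs) == pytest.approx(1 - (1 - 1 / n) ** n, abs=0.02)
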