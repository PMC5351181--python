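import numpy as np
import pytest

from imbforest.datasets import LabeledDataset, imbalance_ratio, make_circle_data
from imbforest.resample import (SAMPLERS, BorderlineSmote1, CentroidSmote,
                                CureSmote, KMeansSmote, RandomOversampler,
                                SafeLevelSmote, Smote, replay_synthetic)


def in_hull_2d(points, hull_points, tol=1e-9):
    """Membership in the convex hull of 2-D points via scipy Delaunay."""
    from scipy.spatial import Delaunay
    tri = Delaunay(hull_points)
    return tri.find_simplex(points - 0.0) >= 0 if tol == 0 else \
        Delaunay(hull_points).find_simplex(points) >= 0


@pytest.fixture(params=list(SAMPLERS))
def sampler_name(request):
    return request.param


class TestSharedContract:
    def test_originals_preserved_and_target_reached(self, sampler_name,
                                                    tiny_imbalanced_ds):
        ds = tiny_imbalanced_ds
        res = SAMPLERS[sampler_name](random_state=3).sample(ds)
        out = res.dataset
        if sampler_name == "cure":  # returned in min-max normalized space
            from imbforest.datasets import min_max_normalize
            expected = min_max_normalize(ds).features
        else:
            expected = ds.features
        np.testing.assert_array_equal(out.features[:ds.n], expected)
        np.testing.assert_array_equal(out.labels[:ds.n], ds.labels)
        assert res.achieved_ir > 0.7
        assert res.achieved_ir == imbalance_ratio(out)
        assert len(res.synthetic_index) == out.n - ds.n
        assert all(out.labels[i] == 1 for i in res.synthetic_index)

    def test_originals_preserved_cure_normalized_space(self,
                                                       tiny_imbalanced_ds):
        # CURE-SMOTE returns normalized space: originals match the
        # normalized input rows, verbatim and in order
        from imbforest.datasets import min_max_normalize
        ds = tiny_imbalanced_ds
        res = CureSmote(n_clusters=2, random_state=3).sample(ds)
        np.testing.assert_array_equal(res.dataset.features[:ds.n],
                                      min_max_normalize(ds).features)

    def test_same_seed_identical_result(self, sampler_name,
                                        tiny_imbalanced_ds):
        r1 = SAMPLERS[sampler_name](random_state=11).sample(tiny_imbalanced_ds)
        r2 = SAMPLERS[sampler_name](random_state=11).sample(tiny_imbalanced_ds)
        np.testing.assert_array_equal(r1.dataset.features, r2.dataset.features)
        assert [p.rand for p in r1.provenance] == [p.rand for p in r2.provenance]

    def test_provenance_replays_bitwise(self, sampler_name,
                                        tiny_imbalanced_ds):
        res = SAMPLERS[sampler_name](random_state=7).sample(tiny_imbalanced_ds)
        for i, rec in zip(res.synthetic_index, res.provenance):
            assert np.array_equal(replay_synthetic(rec),
                                  res.dataset.features[i])

    def test_noop_when_already_balanced(self, sampler_name):
        rng = np.random.RandomState(0)
        ds = LabeledDataset(rng.normal(size=(40, 2)),
                            [0] * 20 + [1] * 20, positive_label=1)
        res = SAMPLERS[sampler_name](random_state=0).sample(ds)
        assert len(res.synthetic_index) == 0
        assert res.dataset.n == 40

    def test_segment_bounds(self, sampler_name, tiny_imbalanced_ds):
        # each synthetic point is a convex combination of its origin and
        # anchor: coordinatewise min/max bounds hold
        res = SAMPLERS[sampler_name](random_state=5).sample(tiny_imbalanced_ds)
        for rec in res.provenance:
            lo = np.minimum(rec.origin, rec.anchor) - 1e-12
            hi = np.maximum(rec.origin, rec.anchor) + 1e-12
            row = replay_synthetic(rec)
            assert np.all(row >= lo) and np.all(row <= hi)

    def test_single_class_rejected(self, sampler_name):
        ds = np.zeros((5, 2)), np.zeros(5)
        with pytest.raises(ValueError):
            SAMPLERS[sampler_name]().fit_resample(*ds)


class TestRandomOversampler:
    def test_exact_count_under_strict_stop_rule(self):
        # 1 minority vs 10 majority at target 0.7: 7 copies give 8/10 = 0.8
        X = np.arange(22.0).reshape(11, 2)
        y = np.array([0] * 10 + [1])
        Xr, yr = RandomOversampler(random_state=0).fit_resample(X, y)
        assert (yr == 1).sum() == 8
        assert len(yr) == 18

    def test_duplicates_only(self, tiny_imbalanced_ds):
        res = RandomOversampler(random_state=2).sample(tiny_imbalanced_ds)
        originals = {tuple(r) for r in
                     tiny_imbalanced_ds.features[tiny_imbalanced_ds.labels == 1]}
        for i in res.synthetic_index:
            assert tuple(res.dataset.features[i]) in originals


class TestSmote:
    def test_interpolation_formula(self):
        rec_origin = np.array([0.0, 0.0])
        rec_anchor = np.array([1.0, 0.0])
        from imbforest.resample import ProvenanceRecord
        rec = ProvenanceRecord("smote", 0, rec_origin, rec_anchor, 0.3)
        np.testing.assert_allclose(replay_synthetic(rec), [0.3, 0.0])

    def test_identical_minority_points(self):
        X = np.vstack([np.random.RandomState(0).normal(size=(30, 2)),
                       np.tile([9.0, 9.0], (6, 1))])
        y = np.array([0] * 30 + [1] * 6)
        res = Smote(random_state=1).sample(LabeledDataset(X, y))
        for i in res.synthetic_index:
            np.testing.assert_allclose(res.dataset.features[i], [9.0, 9.0])

    def test_k_reduced_with_warning(self):
        X = np.vstack([np.zeros((20, 2)), [[1, 1], [1.1, 1], [1, 1.1]]])
        y = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing k"):
            Smote(k_neighbors=5, random_state=0).sample(
                LabeledDataset(X + np.random.RandomState(3).normal(
                    scale=0.01, size=X.shape), y))


class TestBorderlineSmote1:
    def test_neighbourhood_classification_rules(self):
        # minority point surrounded by majority -> noisy; deep inside the
        # minority blob -> safe; on the boundary -> danger
        rng = np.random.RandomState(4)
        minority = rng.normal([0, 0], 0.3, size=(30, 2))
        majority = rng.normal([2.5, 0], 0.3, size=(60, 2))
        lone = np.array([[8.0, 8.0]])          # all-majority neighbourhood
        boundary = np.array([[1.55, 0.0]])     # between the blobs
        X = np.vstack([majority, np.vstack([minority, lone, boundary])])
        y = np.array([0] * 60 + [1] * 32)
        cls = BorderlineSmote1.classify_minority(X, y, 1, 20)
        assert cls[90] == "noisy"
        assert cls[91] == "danger"
        assert sum(v == "safe" for v in cls.values()) > 20

    def test_origins_restricted_to_danger(self):
        rng = np.random.RandomState(4)
        minority = rng.normal([0, 0], 0.3, size=(30, 2))
        majority = rng.normal([0.9, 0], 0.4, size=(90, 2))
        X = np.vstack([majority, minority])
        y = np.array([0] * 90 + [1] * 30)
        sampler = BorderlineSmote1(random_state=1)
        res = sampler.sample(LabeledDataset(X, y))
        cls = BorderlineSmote1.classify_minority(X, y, 1, 20)
        danger = {i for i, v in cls.items() if v == "danger"}
        assert danger  # the fixture does contain boundary points
        assert {rec.origin_index for rec in res.provenance} <= danger

    def test_fallback_when_no_danger_points(self):
        rng = np.random.RandomState(5)
        minority = rng.normal([0, 0], 0.1, size=(30, 2))
        majority = rng.normal([50, 50], 0.1, size=(60, 2))
        X = np.vstack([majority, minority])
        y = np.array([0] * 60 + [1] * 30)
        with pytest.warns(UserWarning, match="no danger points"):
            res = BorderlineSmote1(random_state=0).sample(LabeledDataset(X, y))
        assert res.achieved_ir > 0.7


class TestSafeLevelSmote:
    def test_gap_rule_cases(self):
        rng = np.random.RandomState(0)
        sl = SafeLevelSmote.gap
        assert sl(0, 0, rng) is None
        assert sl(3, 0, rng) == 0.0
        draws_eq = [sl(4, 4, rng) for _ in range(200)]
        assert 0 <= min(draws_eq) and max(draws_eq) <= 1 and max(draws_eq) > 0.9
        draws_gt = [sl(8, 2, rng) for _ in range(200)]
        assert max(draws_gt) <= 0.25
        draws_lt = [sl(2, 8, rng) for _ in range(200)]
        assert min(draws_lt) >= 0.75

    def test_synthetic_points_emitted(self, tiny_imbalanced_ds):
        res = SafeLevelSmote(random_state=0).sample(tiny_imbalanced_ds)
        assert res.achieved_ir > 0.7


class TestCentroidSmote:
    def test_points_head_toward_minority_mean(self):
        X = np.vstack([np.random.RandomState(1).normal(5, 1, size=(30, 2)),
                       [[0.0, 0.0], [2.0, 0.0]]])
        y = np.array([0] * 30 + [1] * 2)
        res = CentroidSmote(random_state=0).sample(LabeledDataset(X, y))
        for rec in res.provenance:
            np.testing.assert_allclose(rec.anchor, [1.0, 0.0])

    def test_single_minority_point(self):
        X = np.vstack([np.random.RandomState(2).normal(size=(10, 2)),
                       [[7.0, 7.0]]])
        y = np.array([0] * 10 + [1])
        res = CentroidSmote(random_state=0).sample(LabeledDataset(X, y))
        for i in res.synthetic_index:
            np.testing.assert_allclose(res.dataset.features[i], [7.0, 7.0])

    def test_inside_minority_hull(self, tiny_imbalanced_ds):
        ds = tiny_imbalanced_ds
        res = CentroidSmote(random_state=4).sample(ds)
        hull_pts = ds.features[ds.labels == 1]
        syn = res.dataset.features[res.synthetic_index]
        assert in_hull_2d(syn, hull_pts).all()


class TestKMeansSmote:
    def test_no_synthetic_point_between_separated_blobs(self):
        rng = np.random.RandomState(6)
        blob_a = rng.normal([0, 0], 0.2, size=(10, 2))
        blob_b = rng.normal([10, 0], 0.2, size=(10, 2))
        majority = rng.normal([5, 8], 1.0, size=(60, 2))
        X = np.vstack([majority, blob_a, blob_b])
        y = np.array([0] * 60 + [1] * 20)
        res = KMeansSmote(n_clusters=2, random_state=1).sample(
            LabeledDataset(X, y))
        syn = res.dataset.features[res.synthetic_index]
        in_a = in_hull_2d(syn, blob_a)
        in_b = in_hull_2d(syn, blob_b)
        assert np.all(in_a | in_b)

    def test_cluster_count_reduced_with_warning(self):
        X = np.vstack([np.random.RandomState(7).normal(size=(20, 2)),
                       [[5, 5], [5.1, 5], [5, 5.1]]])
        y = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing the cluster count"):
            KMeansSmote(n_clusters=5, random_state=0).sample(
                LabeledDataset(X, y))


class TestCureSmote:
    def test_interpolation_formula(self):
        from imbforest.resample import ProvenanceRecord
        rec = ProvenanceRecord("cure", 0, np.array([0.0, 0.0]),
                               np.array([1.0, 1.0]), 0.5)
        np.testing.assert_allclose(replay_synthetic(rec), [0.5, 0.5])

    def test_outlier_never_origin_nor_anchor(self):
        # a distant minority outlier must be removed by CURE and appear in
        # no provenance record, neither as origin nor near any anchor
        rng = np.random.RandomState(8)
        minority = rng.normal([0.3, 0.3], 0.03, size=(24, 2))
        outlier = np.array([[0.95, 0.95]])
        majority = rng.normal([0.6, 0.6], 0.05, size=(80, 2))
        X = np.vstack([majority, minority, outlier])
        y = np.array([0] * 80 + [1] * 25)
        sampler = CureSmote(n_clusters=2, random_state=2)
        res = sampler.sample(LabeledDataset(X, y))
        outlier_row = 104
        assert outlier_row in (80 + sampler.noise_indices_ - 80).tolist() or \
            outlier_row in sampler.noise_indices_.tolist()
        origins = {rec.origin_index for rec in res.provenance}
        assert outlier_row not in origins
        # anchors (shrunk representatives) stay far from the outlier
        out_norm = sampler.transform(outlier)[0]
        for rec in res.provenance:
            assert np.linalg.norm(rec.anchor - out_norm) > 0.2

    def test_synthetic_inside_retained_minority_hull(self, circle_ds):
        sampler = CureSmote(n_clusters=2, random_state=3)
        res = sampler.sample(circle_ds)
        min_idx = np.flatnonzero(circle_ds.labels == 1)
        retained = np.setdiff1d(min_idx, sampler.noise_indices_)
        hull_pts = res.dataset.features[retained]
        syn = res.dataset.features[res.synthetic_index]
        assert in_hull_2d(syn, hull_pts).all()

    def test_minority_entirely_noise_is_error(self):
        # a single minority point is its own cluster of size 1, below the
        # small-cluster threshold only when the threshold allows; force
        # removal via an aggressive fraction
        rng = np.random.RandomState(9)
        X = np.vstack([rng.normal(size=(30, 2)), [[9.0, 9.0], [9.05, 9.0],
                                                  [-9.0, 9.0]]])
        y = np.array([0] * 30 + [1] * 3)
        sampler = CureSmote(n_clusters=1, small_cluster_fraction=2.0,
                            random_state=0)
        with pytest.raises(ValueError, match="entirely removed as noise"):
            sampler.sample(LabeledDataset(X, y))
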