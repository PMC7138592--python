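"""KNN lesion segmentation: features, training sampling, probabilities
against a brute-force oracle, thresholding and Dice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmlpredict import (
    KNNLesionSegmenter,
    KNNParams,
    TrainingPointSet,
    Volume,
    build_training_set,
    dice,
    extract_features,
    knn_probability,
    segment_subject,
)


def brute_force_knn(query, train_X, train_y, k):
    """Independent oracle: full distance sort with index tie-break."""
    out = np.empty(query.shape[0])
    for i, q in enumerate(query):
        d2 = ((train_X - q) ** 2).sum(axis=1)
        order = sorted(range(len(d2)), key=lambda j: (d2[j], j))
        out[i] = train_y[list(order[:k])].sum() / k
    return out


def make_training(rng, n=50, d=3, lesion_frac=0.3):
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < lesion_frac).astype(int)
    y[0] = 1  # guarantee at least one lesion point
    return TrainingPointSet(features=X, labels=y)


class TestKNNProbability:
    def test_exact_match_lesion_point_k1(self, rng):
        train = make_training(rng)
        q = train.features[np.flatnonzero(train.labels == 1)[:3]]
        assert (knn_probability(q, train, k=1) == 1.0).all()

    def test_k_equals_all_gives_global_fraction(self, rng):
        train = make_training(rng, n=40)
        q = rng.normal(size=(5, 3))
        expected = train.labels.mean()
        np.testing.assert_allclose(
            knn_probability(q, train, k=40), expected
        )

    def test_k_larger_than_training_rejected(self, rng):
        train = make_training(rng, n=10)
        with pytest.raises(ValueError, match="exceeds"):
            knn_probability(rng.normal(size=(2, 3)), train, k=11)

    @pytest.mark.parametrize("k", [1, 3, 7, 20])
    def test_matches_brute_force_oracle(self, rng, k):
        train = make_training(rng, n=80)
        q = rng.normal(size=(30, 3))
        got = knn_probability(q, train, k=k)
        want = brute_force_knn(q, train.features, train.labels, k)
        np.testing.assert_array_equal(got, want)

    def test_probabilities_are_multiples_of_one_over_k(self, rng):
        k = 7
        train = make_training(rng, n=60)
        p = knn_probability(rng.normal(size=(40, 3)), train, k=k)
        np.testing.assert_array_equal(p * k, np.round(p * k))

    def test_tie_break_prefers_lower_training_index(self):
        # two training points exactly equidistant from the query; the
        # lower-index one (lesion) must win
        X = np.array([[1.0], [-1.0], [5.0]])
        y = np.array([1, 0, 0])
        est = KNNLesionSegmenter(k=1).fit(X, y)
        assert est.predict_proba(np.array([[0.0]]))[0] == 1.0
        # swap labels: lower index is now non-lesion
        est = KNNLesionSegmenter(k=1).fit(X, np.array([0, 1, 0]))
        assert est.predict_proba(np.array([[0.0]]))[0] == 0.0

    def test_many_duplicate_points_tie_spill(self):
        # 5 coincident points straddle the k=3 boundary; the 3 lowest
        # indices (labels 1,1,0) must be chosen
        X = np.zeros((5, 2))
        y = np.array([1, 1, 0, 1, 1])
        est = KNNLesionSegmenter(k=3).fit(X, y)
        assert est.predict_proba(np.zeros((1, 2)))[0] == pytest.approx(2 / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 120),
        k=st.integers(1, 10),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_property(self, n, k, seed):
        rng = np.random.default_rng(seed)
        k = min(k, n)
        train = make_training(rng, n=n)
        q = rng.normal(size=(10, 3))
        got = knn_probability(q, train, k=k)
        want = brute_force_knn(q, train.features, train.labels, k)
        np.testing.assert_array_equal(got, want)


@pytest.fixture(scope="module")
def seg_setup(small_cohort):
    """Light KNN config + training set from the session cohort."""
    cfg = KNNParams(k=15, n_lesion_points=400, n_nonlesion_points=2000)
    train = build_training_set(
        small_cohort.subjects[:4], cfg, small_cohort.brain_mask, seed=0
    )
    return small_cohort, cfg, train


class TestExtractFeatures:
    def test_zero_spatial_weighting_kills_coordinates(self, small_cohort):
        cfg = KNNParams(spatial_weighting=0.0)
        s = small_cohort.subjects[0]
        _, feats = extract_features(s, cfg, small_cohort.brain_mask)
        assert (feats[:, 2:] == 0).all()
        assert feats[:, :2].std() > 0

    def test_constant_channel_zscores_to_zero(self, small_cohort):
        s = small_cohort.subjects[0]
        const = s.channels["t1"].with_data(
            np.full_like(s.channels["t1"].data, 7.0)
        )
        from wmlpredict.volumes import SubjectRecord

        s2 = SubjectRecord(
            subject_id="const", channels={"t1": const,
                                          "flair": s.channels["flair"]},
            scores={}, covariates={},
        )
        _, feats = extract_features(s2, KNNParams(),
                                    small_cohort.brain_mask)
        assert (feats[:, 0] == 0).all()

    def test_two_voxel_mask_population_sd_zscores(self):
        # intensities {10, 20}: mean 15, population SD 5 -> z = -1, +1
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 10.0, 20.0
        vol = Volume(data, (2, 2, 2))
        mask = Volume(np.ones((2, 1, 1)), (2, 2, 2))
        from wmlpredict.volumes import SubjectRecord

        s = SubjectRecord("two", {"t1": vol, "flair": vol}, {}, {})
        _, feats = extract_features(s, KNNParams(spatial_weighting=1.0),
                                    mask)
        np.testing.assert_allclose(feats[:, 0], [-1.0, 1.0])
        # coordinates are z-scored the same way (x spans 0 and 2 mm)
        np.testing.assert_allclose(feats[:, 2], [-1.0, 1.0])
        # constant coordinate axes z-score to zero
        np.testing.assert_allclose(feats[:, 3:], 0.0)

    def test_missing_channel_rejected(self, small_cohort):
        cfg = KNNParams(feature_channels=("t1", "nope"))
        with pytest.raises(ValueError, match="missing channels"):
            extract_features(small_cohort.subjects[0], cfg,
                             small_cohort.brain_mask)


class TestBuildTrainingSet:
    def test_configured_counts(self, seg_setup):
        _, cfg, train = seg_setup
        assert (train.labels == 1).sum() == cfg.n_lesion_points
        assert (train.labels == 0).sum() == cfg.n_nonlesion_points

    def test_shortfall_uses_all_and_warns(self, small_cohort, caplog):
        cfg = KNNParams(n_lesion_points=10**7, n_nonlesion_points=100)
        import logging

        with caplog.at_level(logging.WARNING):
            train = build_training_set(
                small_cohort.subjects[:2], cfg, small_cohort.brain_mask,
                seed=0,
            )
        assert "available" in caplog.text
        n_lesion_total = sum(
            int(s.true_lesion_mask.data.sum())
            for s in small_cohort.subjects[:2]
        )
        assert (train.labels == 1).sum() == n_lesion_total

    def test_no_repeats_and_seed_determinism(self, small_cohort):
        cfg = KNNParams(n_lesion_points=100, n_nonlesion_points=500)
        t1 = build_training_set(small_cohort.subjects[:2], cfg,
                                small_cohort.brain_mask, seed=1)
        t2 = build_training_set(small_cohort.subjects[:2], cfg,
                                small_cohort.brain_mask, seed=1)
        t3 = build_training_set(small_cohort.subjects[:2], cfg,
                                small_cohort.brain_mask, seed=2)
        np.testing.assert_array_equal(t1.features, t2.features)
        assert not np.array_equal(t1.features, t3.features)
        assert (t3.labels == 1).sum() == (t1.labels == 1).sum()
        assert len({p for p in t1.provenance}) == t1.n_points

    def test_no_lesion_voxels_rejected(self, small_cohort):
        from wmlpredict.volumes import SubjectRecord

        s = small_cohort.subjects[0]
        empty = s.true_lesion_mask.with_data(
            np.zeros_like(s.true_lesion_mask.data)
        )
        s2 = SubjectRecord("empty", dict(s.channels), {}, {},
                           true_lesion_mask=empty)
        with pytest.raises(ValueError, match="no lesion"):
            build_training_set([s2], KNNParams(), small_cohort.brain_mask)


class TestSegmentSubject:
    def test_threshold_one_gives_empty_mask(self, seg_setup):
        cohort, cfg, train = seg_setup
        seg = segment_subject(cohort.subjects[5], train, cfg,
                              cohort.brain_mask, threshold=1.0)
        assert seg.binary_mask.data.sum() == 0
        assert seg.volume_ml == 0.0

    def test_volume_monotone_in_threshold(self, seg_setup):
        cohort, cfg, train = seg_setup
        vols = [
            segment_subject(cohort.subjects[5], train, cfg,
                            cohort.brain_mask, threshold=t).volume_ml
            for t in (0.3, 0.6, 0.9, 1.0)
        ]
        assert vols == sorted(vols, reverse=True)

    def test_mask_is_strict_threshold_of_probability(self, seg_setup):
        cohort, cfg, train = seg_setup
        seg = segment_subject(cohort.subjects[6], train, cfg,
                              cohort.brain_mask)
        np.testing.assert_array_equal(
            seg.binary_mask.data.astype(bool),
            seg.probability_map.data > seg.threshold,
        )
        vox = cohort.brain_mask.voxel_volume_mm3
        assert seg.volume_ml == pytest.approx(
            seg.binary_mask.data.sum() * vox / 1000.0
        )

    def test_invariant_to_affine_intensity_rescaling(self, seg_setup):
        cohort, cfg, train = seg_setup
        s = cohort.subjects[7]
        from wmlpredict.volumes import SubjectRecord

        rescaled = SubjectRecord(
            subject_id=s.subject_id,
            channels={
                "t1": s.channels["t1"].with_data(
                    3.5 * s.channels["t1"].data + 100.0
                ),
                "flair": s.channels["flair"],
            },
            scores=dict(s.scores),
            covariates=dict(s.covariates),
        )
        a = segment_subject(s, train, cfg, cohort.brain_mask)
        b = segment_subject(rescaled, train, cfg, cohort.brain_mask)
        np.testing.assert_allclose(
            a.probability_map.data, b.probability_map.data
        )


class TestDice:
    def _vol(self, arr):
        return Volume(np.asarray(arr, dtype=np.uint8), (1, 1, 1))

    def test_identical_masks(self):
        m = self._vol(np.random.default_rng(0).integers(0, 2, (4, 4, 4)))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[3] = 1
        assert dice(self._vol(a), self._vol(b)) == 0.0

    def test_half_overlap_closed_form(self):
        a = np.zeros((8, 1, 1)); a[:4] = 1
        b = np.zeros((8, 1, 1)); b[2:6] = 1
        assert dice(self._vol(a), self._vol(b)) == 0.5

    def test_both_empty_defined_as_one(self):
        z = self._vol(np.zeros((2, 2, 2)))
        assert dice(z, z) == 1.0

    def test_non_binary_rejected(self):
        a = Volume(np.full((2, 2, 2), 0.5), (1, 1, 1))
        with pytest.raises(ValueError, match="binary"):
            dice(a, a)
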