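"""ROI selection, classifier training, and replay-evidence extraction."""

import numpy as np
import pytest

from replayplan.mvpa import (RoiMask, RoiSelectionError, TrainingError,
                             WindowError, evidence_cross_correlation,
                             replay_evidence, select_rois,
                             train_category_classifier)
from replayplan.neurogen import (NeuroGenParams, VoxelTimeSeries,
                                 generate_localizer, generate_rest_period)


def _split_half(localizer, params, category, permute=False, seed=0):
    """Held-out discrimination (AUC) of a classifier trained on half the blocks.

    The ROI always comes from the true-label training half; ``permute``
    shuffles only the labels the classifier is trained on, the standard
    permutation control for decoding.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(localizer.labels)
    block_idx = np.flatnonzero(np.isin(labels, ("face", "scene", "object")))
    half = rng.permutation(len(block_idx)) < len(block_idx) // 2
    train_idx, test_idx = block_idx[half], block_idx[~half]
    train_true = VoxelTimeSeries(localizer.data[train_idx],
                                 list(labels[train_idx]))
    face_roi, scene_roi = select_rois(train_true)
    roi = face_roi if category == "face" else scene_roi
    train_labels = labels[train_idx]
    if permute:
        train_labels = rng.permutation(train_labels)
    train = VoxelTimeSeries(localizer.data[train_idx], list(train_labels))
    clf = train_category_classifier(train, roi, category)
    post = clf.evidence(localizer.data[test_idx])
    truth = labels[test_idx] == category
    # AUC via rank statistic
    order = np.argsort(post)
    ranks = np.empty(len(post)); ranks[order] = np.arange(1, len(post) + 1)
    n1, n0 = truth.sum(), (~truth).sum()
    return (ranks[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestRoiSelection:
    def test_planted_populations_are_recovered(self, default_localizer):
        params, loc = default_localizer
        face_roi, scene_roi = select_rois(loc)
        for roi, cat in ((face_roi, "face"), (scene_roi, "scene")):
            planted = set(range(*params.population(cat).indices(params.n_voxels)))
            hit = len(planted & set(roi.voxel_indices)) / len(planted)
            contamination = 1 - len(planted & set(roi.voxel_indices)) / len(roi)
            assert hit >= 0.9 and contamination <= 0.05

    def test_masks_are_disjoint(self, default_localizer):
        _, loc = default_localizer
        face_roi, scene_roi = select_rois(loc)
        assert not set(face_roi.voxel_indices) & set(scene_roi.voxel_indices)

    def test_pure_noise_mask_fraction_matches_the_type_i_rate(self):
        # one-sided p < 0.005 admits ~0.5 % of null voxels per direction
        params = NeuroGenParams(selectivity_amplitude=0.0,
                                n_voxels_per_population=500)
        rng = np.random.default_rng(3)
        fractions = []
        for _ in range(10):
            loc = generate_localizer(params, rng)
            try:
                face_roi, scene_roi = select_rois(loc)
                fractions.append((len(face_roi) + len(scene_roi))
                                 / (2 * params.n_voxels))
            except RoiSelectionError:
                fractions.append(0.0)
        assert np.mean(fractions) == pytest.approx(0.005, abs=0.003)

    def test_a_silent_category_raises(self, rng):
        params = NeuroGenParams()
        loc = generate_localizer(params, rng)
        # erase the scene population's signal entirely
        loc.data[:, params.population("scene")] = rng.standard_normal(
            (loc.n_trs, params.n_voxels_per_population))
        with pytest.raises(RoiSelectionError):
            select_rois(loc)


class TestClassifier:
    def test_separable_data_classify_held_out_blocks(self, default_localizer):
        params, loc = default_localizer
        assert _split_half(loc, params, "face") > 0.9

    def test_permuted_labels_are_at_chance(self):
        params = NeuroGenParams(selectivity_amplitude=2.0)
        rng = np.random.default_rng(11)
        aucs = [
            _split_half(generate_localizer(params, rng), params, "face",
                        permute=True, seed=s)
            for s in range(10)
        ]
        # null AUC se ~ sqrt(n1+n0+1/(12 n1 n0)) per run; 10-run mean is tight
        assert abs(np.mean(aucs) - 0.5) < 3 * 0.1 / np.sqrt(10)

    def test_evidence_is_a_posterior_in_unit_interval(self, default_localizer):
        params, loc = default_localizer
        face_roi, _ = select_rois(loc)
        clf = train_category_classifier(loc, face_roi, "face")
        post = clf.evidence(np.random.default_rng(0).standard_normal(
            (50, params.n_voxels)) * 10)
        assert np.all(post >= 0) and np.all(post <= 1)

    def test_single_class_training_raises(self, default_localizer):
        params, loc = default_localizer
        face_roi, _ = select_rois(loc)
        only_face = VoxelTimeSeries(
            loc.data[np.asarray(loc.labels) == "face"],
            ["face"] * 24)
        with pytest.raises(TrainingError):
            train_category_classifier(only_face, face_roi, "face")

    def test_evidence_ignores_non_roi_voxels(self, default_localizer):
        params, loc = default_localizer
        face_roi, _ = select_rois(loc)
        clf = train_category_classifier(loc, face_roi, "face")
        rng = np.random.default_rng(5)
        data = rng.standard_normal((20, params.n_voxels))
        before = clf.evidence(data)
        outside = np.setdiff1d(np.arange(params.n_voxels), face_roi.voxel_indices)
        data[:, outside] += rng.standard_normal((20, len(outside))) * 100
        assert np.allclose(clf.evidence(data), before)


class _ConstantClassifier:
    def __init__(self, values):
        self._values = np.asarray(values, dtype=float)

    def evidence(self, data):
        return self._values[: len(data)]


class TestReplayEvidence:
    def _rests(self, params, rng, n=3):
        return [generate_rest_period(params, "face", "scene", 2, rng)
                for _ in range(n)]

    def test_constant_posterior_passes_through(self, rng):
        params = NeuroGenParams()
        clf = _ConstantClassifier(np.full(10, 0.7))
        score = replay_evidence(clf, self._rests(params, rng))
        assert score.per_rest == (0.7, 0.7, 0.7)
        assert score.block_mean == pytest.approx(0.7)

    def test_first_five_trs_are_ignored(self, rng):
        params = NeuroGenParams()

        class WindowProbe:
            def evidence(self, data):
                # the classifier only ever sees the 10-TR analysis window
                assert len(data) == 10
                return np.full(len(data), 0.2)

        score = replay_evidence(WindowProbe(), self._rests(params, rng))
        assert score.per_rest == (0.2, 0.2, 0.2)

    def test_block_mean_equals_the_mean_of_all_30_posteriors(self, rng):
        params = NeuroGenParams()
        values = np.linspace(0.05, 0.95, 30)
        chunks = iter([values[:10], values[10:20], values[20:]])

        class Sequenced:
            def evidence(self, data):
                return next(chunks)

        score = replay_evidence(Sequenced(), self._rests(params, rng))
        assert score.block_mean == pytest.approx(values.mean(), abs=1e-12)

    def test_short_rest_period_raises(self, rng):
        params = NeuroGenParams()
        rests = self._rests(params, rng)
        rests[1] = VoxelTimeSeries(rests[1].data[:10], ["rest"] * 10)
        with pytest.raises(WindowError):
            replay_evidence(_ConstantClassifier(np.ones(10)), rests)

    def test_monotone_coupling_across_replay_rates(self, default_localizer):
        """Mean block evidence rises strictly with the injected replay rate."""
        params, loc = default_localizer
        face_roi, _ = select_rois(loc)
        clf = train_category_classifier(loc, face_roi, "face")
        rng = np.random.default_rng(21)
        means = []
        for rate in (0, 2, 4, 8):
            block_means = []
            for _ in range(12):
                rests = [generate_rest_period(params, "face", "scene", rate, rng)
                         for _ in range(3)]
                block_means.append(replay_evidence(clf, rests).block_mean)
            means.append(np.mean(block_means))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_window_makes_evidence_robust_to_strong_spillover(self, default_localizer):
        """Root-category block evidence moves < 0.02 under pre-rest spillover
        up to 5x the selectivity amplitude (2-TR decay): the 5-TR omission
        plus the disjoint-ROI readout insulate the analysis window."""
        params, loc = default_localizer
        face_roi, _ = select_rois(loc)
        clf = train_category_classifier(loc, face_roi, "face")
        rng_a = np.random.default_rng(33)
        rng_b = np.random.default_rng(33)
        quiet = NeuroGenParams(selectivity_amplitude=2.0, spillover_amplitude=0.0)
        loud = NeuroGenParams(selectivity_amplitude=2.0,
                              spillover_amplitude=10.0, spillover_decay_tr=2.0)
        for _ in range(10):
            # stage-I category face; spillover lands in the scene population
            rests_q = [generate_rest_period(quiet, "face", "scene", 2, rng_a)
                       for _ in range(3)]
            rests_l = [generate_rest_period(loud, "face", "scene", 2, rng_b)
                       for _ in range(3)]
            a = replay_evidence(clf, rests_q).block_mean
            b = replay_evidence(clf, rests_l).block_mean
            assert abs(a - b) < 0.02


class TestCrossCorrelation:
    def test_identical_series_correlate_perfectly(self, default_localizer):
        params, loc = default_localizer
        face_roi, scene_roi = select_rois(loc)
        clf = train_category_classifier(loc, face_roi, "face")
        rng = np.random.default_rng(2)
        rests = [generate_rest_period(params, "face", "scene", 1, rng)
                 for _ in range(3)]
        res = evidence_cross_correlation(clf, clf, rests)
        assert res.value == pytest.approx(1.0)

    def test_disjoint_rois_avoid_the_anticorrelation_artifact(self, default_localizer):
        """A shared-ROI face/scene classifier pair anti-correlates more than
        the disjoint-ROI design on the same rest data."""
        params, loc = default_localizer
        face_roi, scene_roi = select_rois(loc)
        face_clf = train_category_classifier(loc, face_roi, "face")
        scene_clf = train_category_classifier(loc, scene_roi, "scene")
        shared = RoiMask("face", np.concatenate([face_roi.voxel_indices,
                                                 scene_roi.voxel_indices]))
        face_shared = train_category_classifier(loc, shared, "face")
        scene_shared = train_category_classifier(
            loc, RoiMask("scene", shared.voxel_indices), "scene")
        rng = np.random.default_rng(9)
        rests = [generate_rest_period(params, "face", "scene", 2, rng)
                 for _ in range(30)]
        disjoint = evidence_cross_correlation(face_clf, scene_clf, rests)
        joint = evidence_cross_correlation(face_shared, scene_shared, rests)
        assert disjoint.value > joint.value
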