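"""Linear SVM pixel segmentation: sampling, fitting, prediction, model
selection and ROC."""

import numpy as np
import pytest

import canopycenter as cc
from canopycenter.svm_segmentation import (
    CvPoint,
    SvmConfig,
    TrainingSet,
    cross_validate_C,
    learning_curve,
    mean_roc,
    roc_auc,
)


def _separable_set():
    X = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
    y = np.array([-1, 1])
    return TrainingSet(X, y)


class TestSampling:
    def _small_scene(self):
        hls = cc.HlsImage(np.zeros((4, 4, 3), dtype=np.uint8))
        roi = np.zeros((4, 4), dtype=np.uint8)
        roi[:2, :2] = 1
        nroi = np.zeros((4, 4), dtype=np.uint8)
        nroi[2:, 2:] = 1
        return hls, cc.BinaryMask(roi), cc.BinaryMask(nroi)

    def test_even_split(self, default_fixture):
        img, truth = default_fixture
        hls = cc.rgb_to_hls(img)
        nroi = cc.training_nroi_mask(truth)
        ts = cc.sample_training_pixels(hls, truth.roi, nroi, n=100, seed=0)
        assert ts.n == 100
        assert (ts.labels == 1).sum() == 50
        assert (ts.labels == -1).sum() == 50

    def test_deterministic_given_seed(self, default_fixture):
        img, truth = default_fixture
        hls = cc.rgb_to_hls(img)
        nroi = cc.training_nroi_mask(truth)
        a = cc.sample_training_pixels(hls, truth.roi, nroi, n=40, seed=9)
        b = cc.sample_training_pixels(hls, truth.roi, nroi, n=40, seed=9)
        assert (a.features == b.features).all() and (a.labels == b.labels).all()

    def test_exhaustive_when_n_equals_region_size(self):
        hls, roi, nroi = self._small_scene()
        hls.pixels[roi.pixels == 1] = (10, 10, 10)
        ts = cc.sample_training_pixels(hls, roi, nroi, n=8, seed=0)
        assert (ts.labels == 1).sum() == 4 and (ts.labels == -1).sum() == 4

    def test_insufficient_region_names_it(self):
        hls, roi, nroi = self._small_scene()
        # n=9 → 4 ROI (available) + 5 N-ROI (only 4 present)
        with pytest.raises(ValueError, match="N-ROI"):
            cc.sample_training_pixels(hls, roi, nroi, n=9, seed=0)

    def test_overlapping_masks_rejected(self):
        hls, roi, _ = self._small_scene()
        with pytest.raises(ValueError, match="overlap"):
            cc.sample_training_pixels(hls, roi, roi, n=4, seed=0)


class TestFitPredict:
    def test_separable_pair_perfect_and_bisecting(self):
        model = cc.fit_linear_svm(_separable_set())
        assert (model.predict(_separable_set().features) == [-1, 1]).all()
        # max-margin boundary is the perpendicular bisector through (5,5,5)
        assert abs(model.decision_function(np.array([[5.0, 5.0, 5.0]]))[0]) < 1e-6

    def test_duplicate_sample_does_not_move_separable_solution(self):
        base = _separable_set()
        dup = TrainingSet(
            np.vstack([base.features, base.features[:1]]),
            np.concatenate([base.labels, base.labels[:1]]),
        )
        grid = np.random.default_rng(0).uniform(0, 10, size=(50, 3))
        m1 = cc.fit_linear_svm(base, SvmConfig(C=10.0))
        m2 = cc.fit_linear_svm(dup, SvmConfig(C=10.0))
        assert (m1.predict(grid) == m2.predict(grid)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cc.fit_linear_svm(TrainingSet(np.zeros((3, 3)), np.array([1, 1, 1])))

    def test_predict_mask_restricted_to_domain(self, default_fixture, trained_model):
        img, truth = default_fixture
        hls = cc.rgb_to_hls(img)
        domain = cc.compute_hls_mask(hls)
        out = cc.predict_mask(trained_model, hls, domain)
        assert (out.pixels <= domain.pixels).all()
        assert set(np.unique(out.pixels)) <= {0, 1}

    def test_predict_mask_empty_domain(self, trained_model):
        hls = cc.HlsImage(np.zeros((5, 5, 3), dtype=np.uint8))
        out = cc.predict_mask(trained_model, hls, cc.BinaryMask.zeros((5, 5)))
        assert out.area == 0

    def test_model_text_roundtrip(self, trained_model, tmp_path):
        cc.save_model(trained_model, tmp_path / "m.txt")
        back = cc.load_model(tmp_path / "m.txt")
        np.testing.assert_allclose(back.w, trained_model.w)
        assert back.b == pytest.approx(trained_model.b)


class TestModelSelection:
    def _clouds(self, n=80, gap=30.0, seed=0):
        rng = np.random.default_rng(seed)
        Xp = rng.normal([90, 40, 230], [5, 10, 8], size=(n, 3))
        Xn = rng.normal([90 - gap, 40 + gap, 230 - gap], [5, 10, 8], size=(n, 3))
        X = np.vstack([Xp, Xn])
        y = np.concatenate([np.ones(n), -np.ones(n)]).astype(int)
        return TrainingSet(X, y)

    def test_separable_clouds_plateau_smallest_wins(self):
        ts = self._clouds(gap=60.0)
        best, pts = cross_validate_C(ts, [1e-3, 0.1, 1, 10], folds=4, seed=0)
        assert all(p.mean_score == 1.0 for p in pts)
        assert best == 1e-3

    def test_single_value_grid(self):
        ts = self._clouds()
        best, pts = cross_validate_C(ts, [0.5], folds=4, seed=0)
        assert best == 0.5 and len(pts) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cross_validate_C(self._clouds(), [], folds=4)

    def test_learning_curve_full_size_matches_cv(self):
        ts = self._clouds(gap=60.0)
        pts = learning_curve(ts, [ts.n], folds=4, seed=0)
        _, cv_pts = cross_validate_C(ts, [SvmConfig().C], folds=4, seed=0)
        assert pts[0].val_score == pytest.approx(cv_pts[0].mean_score)

    def test_learning_curve_separable_always_perfect(self):
        ts = self._clouds(gap=60.0)
        pts = learning_curve(ts, [16, 40, ts.n], folds=4, seed=0)
        assert all(p.val_score == 1.0 for p in pts)

    def test_learning_curve_variance_shrinks_on_noisy_pool(self):
        # overlapping clouds: variance at the largest size <= at the smallest,
        # averaged over 10 seeded repeats
        v_small, v_large = [], []
        for rep in range(10):
            ts = self._clouds(n=150, gap=10.0, seed=rep)
            pts = learning_curve(ts, [24, ts.n], folds=4, seed=rep)
            v_small.append(pts[0].val_var)
            v_large.append(pts[-1].val_var)
        assert np.mean(v_large) <= np.mean(v_small)

    def test_size_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            learning_curve(self._clouds(n=20), [100], folds=4)


class TestRoc:
    def test_perfect_and_inverted(self):
        labels = [-1, -1, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels).auc == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels).auc == 0.0

    @pytest.mark.parametrize(
        "scores, labels, want",
        [
            # 3 of 4 positive-negative pairs concordant (0.4 < 0.45 discordant)
            ([0.1, 0.4, 0.45, 0.8], [-1, 1, -1, 1], 0.75),
            # all 4 pairs concordant
            ([0.1, 0.4, 0.35, 0.8], [-1, 1, -1, 1], 1.0),
            # a tie contributes half a pair: (3 + 0.5) / 4
            ([0.1, 0.4, 0.4, 0.8], [-1, 1, -1, 1], 0.875),
        ],
    )
    def test_hand_computed_pair_counting(self, scores, labels, want):
        assert roc_auc(scores, labels).auc == pytest.approx(want)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_mean_roc_of_identical_folds_matches_single(self, rng):
        s = rng.normal(size=60)
        y = np.where(rng.random(60) < 0.5, 1, -1)
        y[:2] = [1, -1]
        single = roc_auc(s, y)
        avg = mean_roc([s, s], [y, y], grid_points=2001)
        assert avg.auc == pytest.approx(single.auc, abs=5e-3)
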