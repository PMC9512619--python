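"""Detector pipeline: preprocessing, features, SVM, events, scoring, rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA

from fidgetlab import behavior
from fidgetlab.behavior import (
    CropRectangle,
    FeatureBlock,
    FeatureConfig,
    FidgetEvent,
    FrameLabelTrack,
)
from conftest import make_track


class TestPreprocess:
    def test_crop_arithmetic(self):
        frames = np.zeros((3, 100, 100), dtype=np.uint8)
        out = behavior.preprocess_frames(frames, crop=CropRectangle(10, 10, 74, 74))
        assert out.shape == (3, 64, 64)

    def test_gamma_one_is_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.random((2, 40, 40)).astype(np.float32)
        out = behavior.preprocess_frames(frames, gamma=1.0)
        assert np.allclose(out, frames)

    def test_constant_frame_stays_constant(self):
        frames = np.full((1, 40, 40), 120, dtype=np.uint8)
        out = behavior.preprocess_frames(frames, gamma=0.5)
        assert np.ptp(out) == 0

    def test_uint8_scaled_and_power_law(self):
        frames = np.full((1, 8, 8), 64, dtype=np.uint8)
        out = behavior.preprocess_frames(frames, gamma=0.5)
        assert out[0, 0, 0] == pytest.approx(np.sqrt(64 / 255), rel=1e-5)

    def test_crop_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            behavior.preprocess_frames(
                np.zeros((1, 32, 32)), crop=CropRectangle(0, 0, 64, 64)
            )

    def test_degenerate_crop_rejected(self):
        with pytest.raises(ValueError):
            CropRectangle(10, 10, 10, 20)


class TestFeatures:
    def test_hog_dimensionality(self):
        # 64x64 frame, 32-px cells, 8 bins -> (64/32)^2 * 8 = 32 features
        frames = np.random.default_rng(0).random((2, 64, 64))
        feats = behavior.compute_hog_features(frames)
        assert feats.shape == (2, 32)

    def test_constant_frames_zero_hog(self):
        feats = behavior.compute_hog_features(np.full((2, 64, 64), 0.5))
        assert np.all(feats == 0)

    def test_frame_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            behavior.compute_hog_features(np.zeros((1, 16, 16)))

    def test_block_vector_length(self):
        # 30 fps, 50 PCA components -> 30 * 50 = 1500 per 1-s block
        rng = np.random.default_rng(1)
        frames = rng.random((90, 96, 96))
        blocks, pca = behavior.extract_block_features(frames, FeatureConfig())
        assert len(blocks) == 3
        assert blocks[0].vector.shape == (1500,)
        assert blocks[2].frame_span == (60, 90)

    def test_fewer_frames_than_block_warns_empty(self):
        frames = np.random.default_rng(0).random((10, 64, 64))
        with pytest.warns(UserWarning, match="fewer frames"):
            blocks, _ = behavior.extract_block_features(frames, FeatureConfig())
        assert blocks == []

    def test_pca_basis_reused_not_refit(self):
        # inference must project with the training basis: projecting new
        # frames through a refit basis gives different features
        def moving_blob(n, speed, size=96):
            yy, xx = np.mgrid[0:size, 0:size]
            return np.stack(
                [
                    np.exp(
                        -(((yy - 48) ** 2 + (xx - 20 - speed * t) ** 2) / (2 * 12.0**2))
                    )
                    for t in range(n)
                ]
            )

        train = moving_blob(60, speed=0.5)
        test = moving_blob(60, speed=-0.8)  # different motion statistics
        _, pca_train = behavior.extract_block_features(train, FeatureConfig())
        blocks_fixed, _ = behavior.extract_block_features(
            test, FeatureConfig(), pca=pca_train
        )
        blocks_refit, _ = behavior.extract_block_features(test, FeatureConfig())
        assert not np.allclose(blocks_fixed[0].vector, blocks_refit[0].vector)


class TestBlockLabels:
    def test_fidget_fraction_threshold(self):
        labels = ["resting"] * 60
        labels[30:40] = ["fidget"] * 10  # 10/30 of block 1
        out = behavior.block_labels_from_frames(make_track(labels), fidget_majority=0.25)
        assert out == ["resting", "fidget"]
        out_strict = behavior.block_labels_from_frames(
            make_track(labels), fidget_majority=0.5
        )
        assert out_strict == ["resting", "resting"]

    def test_modal_non_fidget_label(self):
        labels = ["movement"] * 20 + ["resting"] * 10
        assert behavior.block_labels_from_frames(make_track(labels)) == ["movement"]


def _toy_blocks(n_per_class=12, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i, label in enumerate(["fidget", "movement", "resting"]):
        center = np.zeros(dim)
        center[i] = 10.0
        for j in range(n_per_class):
            xs.append(center + 0.1 * rng.standard_normal(dim))
            ys.append(label)
    blocks = [FeatureBlock(x, i, (i * 30, (i + 1) * 30)) for i, x in enumerate(xs)]
    return blocks, ys


class TestDetectorTraining:
    def test_separable_classes_fit_perfectly(self):
        blocks, ys = _toy_blocks()
        model = behavior.train_detector(blocks, ys, pca=PCA(2), cv_folds=3)
        X = np.stack([b.vector for b in blocks])
        assert (model.svm.predict(X) == np.asarray(ys)).all()

    def test_grid_selection_attains_max_cv_score(self):
        blocks, ys = _toy_blocks()
        model = behavior.train_detector(
            blocks, ys, pca=PCA(2), C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), cv_folds=3
        )
        table = model.cv_results
        best = table.loc[table.rank_test_score == 1].iloc[0]
        assert best.mean_test_score == table.mean_test_score.max()
        assert model.svm.C in (1.0, 10.0) and model.svm.gamma in (0.01, 0.1)

    def test_empty_grid_rejected(self):
        blocks, ys = _toy_blocks()
        with pytest.raises(ValueError, match="grid"):
            behavior.train_detector(blocks, ys, pca=PCA(2), C_grid=())

    def test_single_class_rejected(self):
        blocks, _ = _toy_blocks()
        with pytest.raises(ValueError, match="single class"):
            behavior.train_detector(blocks, ["resting"] * len(blocks), pca=PCA(2))

    def test_serialization_round_trip(self, tmp_path):
        blocks, ys = _toy_blocks()
        model = behavior.train_detector(blocks, ys, pca=PCA(2), cv_folds=3)
        path = tmp_path / "model.zip"
        model.save(path)
        loaded = behavior.DetectorModel.load(path)
        X = np.stack([b.vector for b in blocks])
        assert (loaded.svm.predict(X) == model.svm.predict(X)).all()
        assert loaded.feature_config == model.feature_config


class TestPredictLabels:
    def _model(self):
        blocks, ys = _toy_blocks()
        return behavior.train_detector(blocks, ys, pca=PCA(2), cv_folds=3)

    def test_block_broadcast_to_frames(self):
        # a fidget prediction at block 3 labels frames 90-119
        model = self._model()
        fid = FeatureBlock(np.array([10.0, 0, 0, 0, 0, 0]), 3, (90, 120))
        track = behavior.predict_labels(model, [fid], n_frames=150)
        assert set(np.flatnonzero(track.labels == "fidget")) == set(range(90, 120))
        assert (track.labels[120:] == "resting").all()

    def test_trailing_frames_default_resting(self):
        model = self._model()
        track = behavior.predict_labels(model, [], n_frames=45)
        assert (track.labels == "resting").all()

    def test_feature_mismatch_rejected(self):
        model = self._model()
        bad = FeatureBlock(np.zeros(4), 0, (0, 30))
        with pytest.raises(ValueError, match="feature length"):
            behavior.predict_labels(model, [bad], n_frames=30)


class TestExtractEvents:
    def test_run_length_enumeration(self):
        labels = np.array(["resting"] * 9)
        labels[[1, 2, 3, 6, 7]] = "fidget"
        events = behavior.extract_events(
            make_track(labels), min_duration_frames=2, merge_gap_frames=0
        )
        assert [(e.onset_frame, e.offset_frame) for e in events] == [(1, 4), (6, 8)]

    def test_min_duration_filters(self):
        labels = np.array(["resting"] * 9)
        labels[[1, 2, 3, 6, 7]] = "fidget"
        events = behavior.extract_events(
            make_track(labels), min_duration_frames=3, merge_gap_frames=0
        )
        assert [(e.onset_frame, e.offset_frame) for e in events] == [(1, 4)]

    def test_merge_gap_joins_runs(self):
        labels = np.array(["resting"] * 12)
        labels[[1, 2, 3, 6, 7, 8]] = "fidget"
        events = behavior.extract_events(
            make_track(labels), min_duration_frames=1, merge_gap_frames=2
        )
        assert [(e.onset_frame, e.offset_frame) for e in events] == [(1, 9)]

    def test_no_fidget_frames(self):
        assert behavior.extract_events(make_track(["resting"] * 5)) == []

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_duration_sum_invariant(self, mask):
        # merge_gap=0, min_duration=1: total event duration == fidget frames
        labels = np.where(mask, "fidget", "resting")
        events = behavior.extract_events(
            make_track(labels), min_duration_frames=1, merge_gap_frames=0
        )
        assert sum(e.duration_frames for e in events) == int(np.sum(mask))


class TestScoreDetection:
    def test_perfect_match(self):
        ev = [FidgetEvent(0, 10), FidgetEvent(50, 60)]
        m = behavior.score_detection(ev, ev)
        assert m.precision == 1.0 and m.recall == 1.0

    def test_partial_overlap_enumeration(self):
        truth = [FidgetEvent(0, 10), FidgetEvent(50, 60)]
        pred = [FidgetEvent(5, 12), FidgetEvent(100, 110)]
        m = behavior.score_detection(pred, truth)
        assert m.recall == 0.5 and m.precision == 0.5

    def test_no_predictions_flagged(self):
        m = behavior.score_detection([], [FidgetEvent(0, 10)])
        assert m.recall == 0.0 and not m.precision_defined

    def test_no_truth_flagged(self):
        m = behavior.score_detection([FidgetEvent(0, 10)], [])
        assert not m.recall_defined

    @given(
        st.lists(st.integers(0, 180), min_size=1, max_size=6),
        st.lists(st.integers(0, 180), min_size=1, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_swap_symmetry(self, a_onsets, b_onsets):
        # swapping prediction and truth swaps precision and recall
        def mk(onsets):
            out, last = [], -10
            for o in sorted(onsets):
                o = max(o, last + 1)
                out.append(FidgetEvent(o, o + 5))
                last = o + 5
            return out

        a, b = mk(a_onsets), mk(b_onsets)
        m1 = behavior.score_detection(a, b)
        m2 = behavior.score_detection(b, a)
        assert m1.precision == pytest.approx(m2.recall)
        assert m1.recall == pytest.approx(m2.precision)

    def test_frame_level_counts(self):
        truth = [FidgetEvent(0, 10)]
        pred = [FidgetEvent(5, 15)]
        m = behavior.score_detection(pred, truth, level="frame", n_frames=20)
        assert m.precision == 0.5 and m.recall == 0.5


class TestNormalizedFidgetRate:
    def _table(self):
        # three 1-min epochs: gray at 1/min, gratings at 2/min, gray fill
        return pd.DataFrame(
            {
                "start_frame": [0, 1800, 3600],
                "end_frame": [1800, 3600, 5400],
                "stimulus_type": ["gray", "drifting_grating", "gray"],
                "direction_deg": [np.nan, 0.0, np.nan],
                "temporal_frequency_hz": [np.nan, 1.0, np.nan],
            }
        )

    def test_formula_arithmetic(self):
        # gray 1/min, grating 2/min, per-epoch rates (1, 2, 1) -> SD ~0.471
        events = [FidgetEvent(100, 120), FidgetEvent(2000, 2020), FidgetEvent(2500, 2520),
                  FidgetEvent(4000, 4020)]
        out = behavior.normalized_fidget_rate(events, self._table())
        rates = dict(zip(out.stimulus_type, out.rate_per_min))
        norm = dict(zip(out.stimulus_type, out.normalized_rate))
        sd = np.std([1.0, 2.0, 1.0])
        assert rates["gray"] == pytest.approx(1.0)
        assert rates["drifting_grating"] == pytest.approx(2.0)
        assert norm["drifting_grating"] == pytest.approx((2.0 - 1.0) / sd)
        assert norm["gray"] == pytest.approx(0.0)

    def test_epoch_rate_at_baseline_is_zero(self):
        # per-epoch rates (0, 1, 2)/min: grating rate equals the mean gray
        # rate, so its normalized rate is exactly 0
        events = [FidgetEvent(2000, 2020), FidgetEvent(4000, 4020), FidgetEvent(4100, 4120)]
        out = behavior.normalized_fidget_rate(events, self._table())
        norm = dict(zip(out.stimulus_type, out.normalized_rate))
        assert norm["drifting_grating"] == pytest.approx(0.0)

    def test_no_gray_epochs_rejected(self):
        table = self._table()
        table["stimulus_type"] = "drifting_grating"
        with pytest.raises(ValueError, match="gray"):
            behavior.normalized_fidget_rate([], table)

    def test_zero_sd_flagged(self):
        events = [FidgetEvent(100, 120), FidgetEvent(2000, 2020), FidgetEvent(4000, 4020)]
        table = self._table()
        out = behavior.normalized_fidget_rate(events, table)
        assert out.attrs["undefined"]
        assert out.normalized_rate.isna().all()
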