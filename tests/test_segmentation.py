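"""Segmentation: architecture shape, training loop, detection, metrics, I/O."""

import numpy as np
import pytest

from fetalsweep.preprocess import Frame, TrainingSet
from fetalsweep.segmentation import (ConfigurationError, OracleSegmenter,
                                     SegModel, UNetConfig, build_unet,
                                     detect_series, dice_coefficient,
                                     jaccard_index, load_model, predict_mask,
                                     save_model, segmentation_metrics,
                                     train_segmenter, train_val_split)


def square_dataset(n=24, size=16, seed=0, all_background=False):
    """Frames with a bright square; mask = the square. Trivially learnable."""
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0.0, 0.3, size=(n, size, size)).astype(np.float32)
    masks = np.zeros((n, size, size), bool)
    present = np.zeros(n, bool)
    for i in range(n):
        if all_background or i % 3 == 0:
            continue
        r, c = rng.integers(2, size - 7, size=2)
        frames[i, r:r + 5, c:c + 5] = rng.uniform(0.8, 1.0)
        masks[i, r:r + 5, c:c + 5] = True
        present[i] = True
    return TrainingSet(frames=frames, masks={"head": masks},
                       present={"head": present},
                       patient_ids=np.arange(n) % 3)


class TestArchitecture:
    def test_default_depth4_has_23_conv_layers(self):
        model = build_unet(UNetConfig(input_size=(16, 16), depth=4, base_filters=2))
        assert model.conv_layer_count == 23

    def test_conv_count_formula_5d_plus_3(self):
        for depth, size in ((2, 16), (3, 16)):
            model = build_unet(UNetConfig(input_size=(size, size), depth=depth,
                                          base_filters=2))
            assert model.conv_layer_count == 5 * depth + 3

    def test_filters_double_per_level(self):
        model = build_unet(UNetConfig(input_size=(16, 16), depth=3, base_filters=4))
        down_out = [block.layers[0].c_out for block in model.net.down]
        assert down_out == [4, 8, 16]
        assert model.net.bottleneck.layers[0].c_out == 32

    def test_forward_shape_and_range(self):
        model = build_unet(UNetConfig(input_size=(16, 16), depth=2, base_filters=2))
        x = np.random.default_rng(0).random((3, 1, 16, 16)).astype(np.float32)
        out = model.net.forward(x)
        assert out.shape == (3, 1, 16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            UNetConfig(input_size=(100, 100), depth=4)

    def test_predict_proba_shape_check(self):
        model = build_unet(UNetConfig(input_size=(16, 16), depth=2, base_filters=2))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 8, 8), np.float32))

    def test_seed_determines_weights(self):
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2, seed=5)
        a, b = build_unet(cfg), build_unet(cfg)
        for pa, pb in zip(a.net.params, b.net.params):
            assert np.array_equal(pa.value, pb.value)


class TestOverlapCoefficients:
    def test_both_empty_is_one(self):
        empty = np.zeros((4, 4), bool)
        assert dice_coefficient(empty, empty) == 1.0
        assert jaccard_index(empty, empty) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_coefficient(a, b) == 0.0
        assert jaccard_index(a, b) == 0.0

    def test_half_overlap_values(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :2] = True           # area 2
        b[0, :4] = True           # area 4, intersection 2
        assert dice_coefficient(a, b) == pytest.approx(2 * 2 / 6)
        assert jaccard_index(a, b) == pytest.approx(2 / 4)

    def test_dice_jaccard_relation(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        d, j = dice_coefficient(a, b), jaccard_index(a, b)
        assert d == pytest.approx(2 * j / (1 + j))


class TestSplit:
    def test_80_20_of_positives(self):
        present = np.zeros(50, bool)
        present[:20] = True
        train_idx, val_idx = train_val_split(present, seed=0)
        assert len(val_idx) == 4            # 20% of 20 positives
        assert present[val_idx].all()
        assert not np.intersect1d(train_idx, val_idx).size
        assert len(train_idx) + len(val_idx) == 50

    def test_negatives_all_stay_in_training(self):
        present = np.zeros(30, bool)
        present[10:20] = True
        train_idx, _ = train_val_split(present, seed=1)
        assert set(np.flatnonzero(~present)) <= set(train_idx)

    def test_seeded_and_reproducible(self):
        present = np.zeros(40, bool)
        present[::2] = True
        a = train_val_split(present, seed=3)
        b = train_val_split(present, seed=3)
        c = train_val_split(present, seed=4)
        assert np.array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])


class TestTraining:
    def test_loss_decreases_on_learnable_problem(self):
        ds = square_dataset()
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=4,
                         batch_size=8, epochs=5, seed=0)
        model = train_segmenter(ds, cfg, "head")
        h = model.history
        assert len(h["epoch"]) == 5
        assert h["train_loss"][-1] < h["train_loss"][0]
        assert np.isfinite(h["val_dice"]).all()

    def test_training_is_deterministic(self):
        ds = square_dataset()
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         batch_size=8, epochs=2, seed=1)
        m1 = train_segmenter(ds, cfg, "head")
        m2 = train_segmenter(ds, cfg, "head")
        assert m1.history["train_loss"] == m2.history["train_loss"]
        for p1, p2 in zip(m1.net.params, m2.net.params):
            assert np.array_equal(p1.value, p2.value)

    def test_all_background_fallback_warns(self):
        ds = square_dataset(all_background=True)
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         batch_size=8, epochs=1, seed=0)
        model = train_segmenter(ds, cfg, "head")
        assert "warning" in model.history

    def test_size_mismatch_rejected(self):
        ds = square_dataset(size=16)
        cfg = UNetConfig(input_size=(32, 32), depth=2, base_filters=2, epochs=1)
        from fetalsweep.segmentation import TrainingError
        with pytest.raises(TrainingError):
            train_segmenter(ds, cfg, "head")


class TestOracle:
    def test_exact_truth_at_native_resolution(self, default_phantom):
        _, exam, truth = default_phantom
        oracle = OracleSegmenter(truth, "head")
        frame = exam.sweeps[2][5]
        prob, binary = predict_mask(oracle, frame)
        assert np.array_equal(binary, truth.masks[2]["head"][5])

    def test_resizes_for_preprocessed_frames(self, default_phantom):
        _, exam, truth = default_phantom
        from fetalsweep.preprocess import crop_and_resize
        oracle = OracleSegmenter(truth, "placenta")
        small, _ = crop_and_resize(exam.sweeps[1][0], out_size=(64, 64))
        prob, binary = predict_mask(oracle, small)
        assert binary.shape == (64, 64)

    def test_prediction_shape_contract_enforced(self):
        class Bad:
            def predict_frame(self, frame):
                return np.zeros((2, 2))

        with pytest.raises(ValueError):
            predict_mask(Bad(), Frame(np.zeros((8, 8)), 1.0))


class TestDetectSeries:
    def test_area_threshold(self):
        stack = np.zeros((6, 10, 10), bool)
        stack[1:5, :3, :3] = True        # area 9 < 30 -> filtered
        out = detect_series(stack, min_area_px=30, min_run=1)
        assert not out.present.any()

    def test_short_run_removed_long_run_kept(self):
        stack = np.zeros((10, 10, 10), bool)
        stack[1, :6, :6] = True                       # isolated hit
        for i in (4, 5, 6, 7):
            stack[i, :6, :6] = True                   # run of 4
        out = detect_series(stack, min_area_px=30, min_run=3)
        assert not out.present[1]
        assert out.present[4:8].all()

    def test_depth_centroid_normalized(self):
        stack = np.zeros((4, 11, 11), bool)
        for i in range(3):
            stack[i, 10, :] = True                    # deepest row only
        out = detect_series(stack, min_area_px=5, min_run=3)
        assert out.depth_centroid[0] == pytest.approx(1.0)
        assert np.isnan(out.depth_centroid[3])

    def test_area_zeroed_where_absent(self):
        stack = np.zeros((3, 8, 8), bool)
        stack[0, :4, :4] = True
        out = detect_series(stack, min_area_px=5, min_run=3)
        assert (out.area_px == 0).all()


class TestMetrics:
    def test_perfect_prediction(self):
        truth = np.zeros((6, 12, 12), bool)
        truth[2:5, 3:9, 3:9] = True
        m = segmentation_metrics(truth, truth)
        for key in ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                    "jaccard", "dice", "pixel_accuracy"):
            assert m[key] == 1.0
        assert m["area_error_pct"] == 0.0

    def test_known_confusion(self):
        truth = np.zeros((4, 5, 5), bool)
        pred = np.zeros((4, 5, 5), bool)
        truth[0, :2, :2] = True; pred[0, :2, :2] = True     # TP
        truth[1, :2, :2] = True                             # FN
        pred[2, :2, :2] = True                              # FP
        m = segmentation_metrics(pred, truth)
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["accuracy"] == 0.5

    def test_no_positive_truth_flags_pixel_metrics_undefined(self):
        empty = np.zeros((3, 6, 6), bool)
        m = segmentation_metrics(empty, empty)
        assert not m["pixel_metrics_defined"]
        assert np.isnan(m["jaccard"])
        assert m["specificity"] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((2, 4, 4)), np.zeros((3, 4, 4)))


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        ds = square_dataset()
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         batch_size=8, epochs=1, seed=2)
        model = train_segmenter(ds, cfg, "head")
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        x = ds.frames[:4]
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))
        assert loaded.structure == "head"
        assert loaded.history["train_loss"] == model.history["train_loss"]
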