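"""Detector: score-map contracts, IoU/NMS, PR evaluation, k-fold splits."""

import numpy as np
import pytest

from sealface import detection
from sealface.annotations import AnnotatedScene, FaceAnnotation
from sealface.detection import (Detection, DetectorConfig, build_detector,
                                detect, evaluate_detector, iou, nms,
                                stratified_kfold, train_detector,
                                load_detector, save_detector)
from sealface.synth import make_identities, render_scene


class TestIoU:
    def test_identical(self):
        assert iou((3, 4, 10, 10), (3, 4, 10, 10)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 5, 5), (10, 10, 5, 5)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou((0, 0, 2, 2), (1, 0, 2, 2)) == pytest.approx(2 / 6)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 2, 2))


class TestScoreMapContracts:
    @pytest.mark.parametrize("size,expected", [(256, 32), (250, 32),
                                               (128, 16), (100, 13)])
    def test_stride8_ceil_shape(self, size, expected):
        model = build_detector()
        x = np.zeros((1, 1, size, size), dtype=np.float32)
        scores, feat = model.forward(x)
        assert scores.shape[2:] == (expected, expected)

    def test_channel_counts(self):
        model = build_detector()
        x = np.zeros((1, 1, 128, 128), dtype=np.float32)
        scores, feat = model.forward(x)
        assert feat.shape[1] == 32
        assert scores.shape[1] == 1

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            DetectorConfig(downsample_factor=4)
        with pytest.raises(ValueError):
            DetectorConfig(output_channels=2)


class TestDetect:
    def test_infinite_threshold_empty(self):
        model = build_detector()
        img = np.random.default_rng(0).integers(0, 255, (128, 128)).astype(np.uint8)
        assert detect(model, img, threshold=np.inf) == []

    def test_intensity_rescaling_invariance(self):
        # per-image standardization makes detection invariant to
        # global affine intensity changes
        model = build_detector()
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 200, (128, 128)).astype(np.float32)
        a = detect(model, img, threshold=-np.inf)
        b = detect(model, img * 1.7 + 11.0, threshold=-np.inf)
        assert [d.box for d in a] == [d.box for d in b]


def greedy_nms_oracle(dets, thr):
    """Independent restatement of the greedy rule: repeatedly take the
    highest-scoring remaining box, drop everything overlapping it."""
    remaining = list(dets)
    kept = []
    while remaining:
        best = max(remaining, key=lambda d: d.score)
        kept.append(best)
        remaining = [d for d in remaining
                     if d is not best and iou(d.box, best.box) <= thr]
    return kept


class TestNms:
    def test_higher_score_survives(self):
        a = Detection(box=(0, 0, 10, 10), score=0.9)
        b = Detection(box=(1, 1, 10, 10), score=0.5)
        assert nms([b, a], 0.5) == [a]

    def test_matches_oracle_up_to_six_boxes(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(1, 7)
            dets = [Detection(box=(float(rng.uniform(0, 40)),
                                   float(rng.uniform(0, 40)),
                                   float(rng.uniform(5, 20)),
                                   float(rng.uniform(5, 20))),
                              score=float(rng.normal()))
                    for _ in range(n)]
            assert nms(dets, 0.3) == greedy_nms_oracle(dets, 0.3)


def _fake_scene(boxes, size=(200, 200), valid=None):
    faces = []
    for i, b in enumerate(boxes):
        l, t, w, h = b
        ok = True if valid is None else valid[i]
        faces.append(FaceAnnotation(
            box=b, left_eye=(l + 0.3 * w, t + 0.4 * h),
            right_eye=(l + 0.7 * w, t + 0.4 * h), valid=ok))
    return AnnotatedScene(image_path="fake.png", image_size=size, faces=faces)


class TestEvaluateDetector:
    def _patched(self, monkeypatch, detections):
        monkeypatch.setattr(detection, "detect",
                            lambda model, image, threshold: detections)

    def test_perfect_predictions(self, monkeypatch):
        boxes = [(10, 10, 30, 30), (100, 100, 30, 30)]
        scene = _fake_scene(boxes)
        self._patched(monkeypatch, [Detection(box=b, score=1.0) for b in boxes])
        rows = evaluate_detector(object(), [scene], thresholds=[0.5],
                                 images={"fake.png": np.zeros((200, 200))})
        assert rows[0]["precision"] == 1.0 and rows[0]["recall"] == 1.0

    def test_no_predictions_precision_one(self, monkeypatch):
        scene = _fake_scene([(10, 10, 30, 30)])
        self._patched(monkeypatch, [])
        rows = evaluate_detector(object(), [scene], thresholds=[0.0],
                                 images={"fake.png": np.zeros((200, 200))})
        assert rows[0]["precision"] == 1.0
        assert rows[0]["recall"] == 0.0

    def test_hand_counted_precision_recall(self, monkeypatch):
        # 4 truths; 3 predictions of which 2 match -> P=2/3, R=1/2
        truths = [(0, 0, 20, 20), (50, 50, 20, 20), (100, 100, 20, 20),
                  (150, 150, 20, 20)]
        scene = _fake_scene(truths)
        preds = [Detection(box=(1, 1, 20, 20), score=0.9),
                 Detection(box=(51, 49, 20, 20), score=0.8),
                 Detection(box=(10, 120, 20, 20), score=0.7)]
        self._patched(monkeypatch, preds)
        rows = evaluate_detector(object(), [scene], thresholds=[0.0],
                                 images={"fake.png": np.zeros((200, 200))})
        assert rows[0]["precision"] == pytest.approx(2 / 3)
        assert rows[0]["recall"] == pytest.approx(0.5)

    def test_requires_annotations(self):
        with pytest.raises(ValueError):
            evaluate_detector(object(), [], thresholds=[0.0])


@pytest.fixture(scope="module")
def tiny_scenes():
    templates = make_identities(4, seed=3)
    images, scenes = {}, []
    for i in range(3):
        img, scene = render_scene(templates, 3, size=(256, 256),
                                  seed=50 + i, image_path=f"t{i}.png",
                                  invalid_fraction=0.0)
        images[scene.image_path] = img
        scenes.append(scene)
    return scenes, images


class TestTrainDetector:

    def test_seeded_training_reproducible(self, tiny_scenes):
        scenes, images = tiny_scenes
        cfg = DetectorConfig(epochs=2, seed=9)
        _, trace_a = train_detector(build_detector(cfg), scenes, cfg, images)
        _, trace_b = train_detector(build_detector(cfg), scenes, cfg, images)
        assert trace_a == trace_b

    def test_zero_epochs_is_noop(self, tiny_scenes):
        scenes, images = tiny_scenes
        cfg = DetectorConfig(epochs=0, seed=9)
        model = build_detector(cfg)
        before = [p.copy() for p, _ in model.params()]
        model, trace = train_detector(model, scenes, cfg, images)
        assert trace == []
        for (p, _), old in zip(model.params(), before):
            np.testing.assert_array_equal(p, old)

    def test_loss_decreases(self, tiny_scenes):
        scenes, images = tiny_scenes
        cfg = DetectorConfig(epochs=4, seed=9)
        _, trace = train_detector(build_detector(cfg), scenes, cfg, images)
        assert trace[-1] < trace[0]

    def test_no_valid_faces_rejected(self):
        scene = _fake_scene([(10, 10, 30, 30)], valid=[False])
        with pytest.raises(ValueError):
            train_detector(build_detector(), [scene],
                           images={"fake.png": np.zeros((200, 200))})

    def test_checkpoint_round_trip(self, tiny_scenes, tmp_path):
        scenes, images = tiny_scenes
        cfg = DetectorConfig(epochs=1, seed=9)
        model, _ = train_detector(build_detector(cfg), scenes, cfg, images)
        save_detector(model, tmp_path / "det.npz")
        back = load_detector(tmp_path / "det.npz")
        img = images[scenes[0].image_path]
        np.testing.assert_allclose(model.score_map(img), back.score_map(img),
                                   atol=1e-6)


class TestStratifiedKfold:
    def test_single_stratum_even_split(self):
        folds = stratified_kfold(list(range(10)), ["a"] * 10, k=5, seed=1)
        assert all(len(val) == 2 for _, val in folds)

    def test_two_strata_counts(self):
        strata = ["A"] * 10 + ["B"] * 5
        folds = stratified_kfold(list(range(15)), strata, k=5, seed=1)
        for _, val in folds:
            assert sum(1 for i in val if strata[i] == "A") == 2
            assert sum(1 for i in val if strata[i] == "B") == 1

    def test_partition_property_over_seeds(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            n = int(rng.integers(6, 40))
            strata = [f"s{int(rng.integers(3))}" for _ in range(n)]
            folds = stratified_kfold(list(range(n)), strata, k=3, seed=seed)
            all_val = [i for _, val in folds for i in val]
            assert sorted(all_val) == list(range(n))  # disjoint + complete
            for train, val in folds:
                assert set(train) == set(range(n)) - set(val)

    def test_small_stratum_warns(self):
        with pytest.warns(UserWarning, match="round-robin"):
            stratified_kfold(list(range(4)), ["a", "a", "a", "b"], k=3)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([1, 2], ["a", "a"], k=1)
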