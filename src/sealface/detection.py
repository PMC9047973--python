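"""Seal-face detection with a small fully-convolutional score-map network.

The detector consumes a grayscale image and produces a single-channel
score map at 1/8 of the input resolution: three stride-2 convolutions
bring the image down by 8 into a 32-channel feature map, four stride-1
convolution + batch-norm + ReLU layers refine it, and a 1x1 linear head
emits one score per stride-8 location.  A large score means "face
here".  Detections are local maxima of the map above a threshold,
mapped to fixed-size windows at the corresponding image positions, with
greedy non-maximum suppression; a small image pyramid (factor sqrt 2)
covers faces larger than the window.

Training uses a max-margin hinge loss on the score map: stride-8
locations whose window overlaps a valid ground-truth face at IoU >= 0.5
must score above +1, hard-mined background locations below -1, and
locations overlapping invalid (ignored) faces or truth boxes
ambiguously contribute nothing.  This is a desk-scale stand-in that
keeps the max-margin character of the MMOD objective the original tool
relies on.

Images are standardized to zero mean / unit variance per image before
the network, so detection is invariant to global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import logging
import warnings

import numpy as np
from scipy import ndimage

from . import nn
from .annotations import AnnotatedScene, load_image

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "Detection",
    "DetectorModel",
    "build_detector",
    "detect",
    "iou",
    "nms",
    "train_detector",
    "evaluate_detector",
    "stratified_kfold",
    "save_detector",
    "load_detector",
]


@dataclass
class DetectorConfig:
    downsample_factor: int = 8           # fixed by the architecture
    feature_channels: int = 32           # channels after the downsampling stack
    post_layers: int = 4                 # conv+BN+ReLU layers at stride 1
    output_channels: int = 1
    detection_window: tuple[int, int] = (64, 64)
    nms_iou: float = 0.25
    threshold: float = 0.0               # default operating point
    n_scales: int = 3                    # image pyramid depth
    pyramid_factor: float = 2.0 ** 0.5
    # training
    epochs: int = 10
    learning_rate: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 1e-4
    positive_iou: float = 0.5
    ignore_iou: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.downsample_factor != 8:
            raise ValueError("the score map is defined at stride 8")
        if self.output_channels != 1:
            raise ValueError("the score map has a single channel")


@dataclass(frozen=True)
class Detection:
    box: tuple[float, float, float, float]  # (left, top, width, height)
    score: float


class DetectorModel:
    """Score-map CNN; see module docstring for the layer plan."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.feature_channels
        down = []
        for cin, cout, k in ((1, ch // 4, 5), (ch // 4, ch // 2, 3),
                             (ch // 2, ch, 3)):
            down += [nn.Conv2d(cin, cout, k, stride=2, rng=rng),
                     nn.BatchNorm2d(cout), nn.ReLU()]
        self.down = nn.Sequential(*down)
        post = []
        for _ in range(config.post_layers):
            post += [nn.Conv2d(ch, ch, 3, stride=1, rng=rng),
                     nn.BatchNorm2d(ch), nn.ReLU()]
        self.post = nn.Sequential(*post)
        self.head = nn.Conv2d(ch, config.output_channels, 1, stride=1, rng=rng)

    def forward(self, x: np.ndarray, train: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """(N,1,H,W) float input -> (score map (N,1,ceil(H/8),ceil(W/8)),
        32-channel intermediate feature map)."""
        feat = self.down.forward(x, train=train)
        out = self.post.forward(feat, train=train)
        return self.head.forward(out, train=train), feat

    def backward(self, grad: np.ndarray) -> None:
        self.down.backward(self.post.backward(self.head.backward(grad)))

    def params(self):
        return self.down.params() + self.post.params() + self.head.params()

    def score_map(self, image: np.ndarray) -> np.ndarray:
        """Inference score map for a 2-D grayscale image."""
        x = standardize(image)[None, None]
        scores, _ = self.forward(x, train=False)
        return scores[0, 0]

    def state_arrays(self):
        out = {}
        for prefix, part in (("down", self.down), ("post", self.post),
                             ("head", self.head)):
            for k, v in part.state_arrays().items():
                out[f"{prefix}.{k}"] = v
        return out


def build_detector(config: DetectorConfig | None = None) -> DetectorModel:
    return DetectorModel(config or DetectorConfig())


def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance float32 copy of a grayscale image."""
    x = np.asarray(image, dtype=np.float32)
    std = x.std()
    return (x - x.mean()) / (std if std > 1e-6 else 1.0)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (left, top, width, height) boxes."""
    la, ta, wa, ha = box_a
    lb, tb, wb, hb = box_b
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        raise ValueError("IoU requires positive-area boxes")
    ix = max(0.0, min(la + wa, lb + wb) - max(la, lb))
    iy = max(0.0, min(ta + ha, tb + hb) - max(ta, tb))
    inter = ix * iy
    return inter / (wa * ha + wb * hb - inter)


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression, highest score first."""
    ordered = sorted(detections, key=lambda d: -d.score)
    kept: list[Detection] = []
    for det in ordered:
        if all(iou(det.box, k.box) <= iou_threshold for k in kept):
            kept.append(det)
    return kept


def _candidates_from_map(scores: np.ndarray, threshold: float,
                         window: tuple[int, int], stride: int,
                         inv_scale: float, image_shape: tuple[int, int]
                         ) -> list[Detection]:
    """Local maxima of a score map above threshold, as image-space boxes."""
    local_max = scores >= ndimage.maximum_filter(scores, size=3)
    ys, xs = np.nonzero(local_max & (scores >= threshold))
    wh, ww = window
    ih, iw = image_shape
    out = []
    for y, x in zip(ys, xs):
        cx = (x + 0.5) * stride * inv_scale
        cy = (y + 0.5) * stride * inv_scale
        w = ww * inv_scale
        h = wh * inv_scale
        left = min(max(cx - w / 2.0, 0.0), iw - 1)
        top = min(max(cy - h / 2.0, 0.0), ih - 1)
        w = min(w, iw - left)
        h = min(h, ih - top)
        out.append(Detection(box=(left, top, w, h),
                             score=float(scores[y, x])))
    return out


def detect(model: DetectorModel, image: np.ndarray,
           threshold: float | None = None) -> list[Detection]:
    """Detect faces in a grayscale image.

    Runs the score map over an image pyramid (``config.n_scales``
    levels shrinking by ``pyramid_factor``), thresholds local maxima,
    and greedily NMS-filters the pooled candidates.  Sorted by
    descending score.
    """
    cfg = model.config
    if threshold is None:
        threshold = cfg.threshold
    image = np.asarray(image, dtype=np.float32)
    if np.isposinf(threshold):
        return []
    candidates: list[Detection] = []
    for level in range(cfg.n_scales):
        scale = cfg.pyramid_factor ** (-level)
        scaled = image if level == 0 else ndimage.zoom(image, scale, order=1)
        if min(scaled.shape) < max(cfg.detection_window):
            break
        scores = model.score_map(scaled)
        candidates += _candidates_from_map(
            scores, threshold, cfg.detection_window, cfg.downsample_factor,
            1.0 / scale, image.shape)
    return nms(candidates, cfg.nms_iou)


def _anchor_targets(scene: AnnotatedScene, map_shape: tuple[int, int],
                    cfg: DetectorConfig) -> np.ndarray:
    """Per-location training label: +1 positive, -1 negative, 0 ignore."""
    hm, wm = map_shape
    labels = -np.ones((hm, wm), dtype=np.float32)
    stride = cfg.downsample_factor
    wh, ww = cfg.detection_window
    ys, xs = np.meshgrid(np.arange(hm), np.arange(wm), indexing="ij")
    cx = (xs + 0.5) * stride
    cy = (ys + 0.5) * stride
    anchors = np.stack([cx - ww / 2, cy - wh / 2,
                        np.full_like(cx, ww, dtype=float),
                        np.full_like(cy, wh, dtype=float)], axis=-1)
    for face in scene.faces:
        fb = face.box
        il = np.maximum(anchors[..., 0], fb[0])
        it = np.maximum(anchors[..., 1], fb[1])
        ir = np.minimum(anchors[..., 0] + anchors[..., 2], fb[0] + fb[2])
        ib = np.minimum(anchors[..., 1] + anchors[..., 3], fb[1] + fb[3])
        inter = np.clip(ir - il, 0, None) * np.clip(ib - it, 0, None)
        union = ww * wh + fb[2] * fb[3] - inter
        overlap = inter / union
        if face.valid:
            labels[(overlap >= cfg.positive_iou)] = 1.0
            amb = (overlap >= cfg.ignore_iou) & (overlap < cfg.positive_iou)
            labels[amb & (labels < 1.0)] = 0.0
        else:
            labels[(overlap >= cfg.ignore_iou) & (labels < 1.0)] = 0.0
    return labels


def _scene_image(scene: AnnotatedScene, images) -> np.ndarray:
    if images is not None:
        return images[scene.image_path]
    return load_image(scene.image_path)


def train_detector(model: DetectorModel, scenes: list[AnnotatedScene],
                   config: DetectorConfig | None = None,
                   images: dict[str, np.ndarray] | None = None
                   ) -> tuple[DetectorModel, list[float]]:
    """Train the detector on annotated scenes; returns (model, loss trace).

    ``images`` optionally maps ``scene.image_path`` to in-memory
    arrays; otherwise images are loaded from disk.  One scene per
    gradient step; per-epoch scene order is shuffled from the seed.
    Invalid-flagged faces are excluded from positives and their
    neighborhoods from negatives.
    """
    cfg = config or model.config
    if not any(scene.valid_faces for scene in scenes):
        raise ValueError("training set contains no valid faces")
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = nn.SGD(model.params(), lr=cfg.learning_rate,
                       momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    cache = [standardize(_scene_image(s, images)) for s in scenes]
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(scenes))
        epoch_loss = 0.0
        for idx in order:
            scene = scenes[idx]
            x = cache[idx][None, None]
            scores, _ = model.forward(x, train=True)
            s = scores[0, 0]
            labels = _anchor_targets(scene, s.shape, cfg)
            grad = np.zeros_like(s)
            loss = 0.0
            pos = labels > 0.5
            n_pos = int(pos.sum())
            if n_pos:
                margin = 1.0 - s[pos]
                active = margin > 0
                loss += float(margin[active].sum()) / n_pos
                gpos = np.zeros(n_pos, dtype=np.float32)
                gpos[active] = -1.0 / n_pos
                grad[pos] = gpos
            neg = labels < -0.5
            if neg.any():
                neg_scores = s[neg]
                n_hard = min(max(8, 3 * n_pos), neg_scores.size)
                hard_idx = np.argpartition(-neg_scores, n_hard - 1)[:n_hard]
                margin = 1.0 + neg_scores[hard_idx]
                active = margin > 0
                loss += float(margin[active].sum()) / n_hard
                gneg = np.zeros(neg_scores.size, dtype=np.float32)
                g = np.zeros(n_hard, dtype=np.float32)
                g[active] = 1.0 / n_hard
                gneg[hard_idx] = g
                grad[neg] = gneg
            model.backward(grad[None, None])
            optimizer.step()
            epoch_loss += loss
        losses.append(epoch_loss / len(scenes))
        logger.info("detector epoch %d/%d loss %.4f",
                    epoch + 1, cfg.epochs, losses[-1])
    return model, losses


def evaluate_detector(model: DetectorModel, scenes: list[AnnotatedScene],
                      thresholds: list[float] | None = None,
                      images: dict[str, np.ndarray] | None = None):
    """Precision/recall over a threshold sweep.

    A prediction matches a ground-truth box when IoU >= 0.5, assigned
    one-to-one greedily by descending score.  Predictions overlapping
    invalid-flagged faces are discarded before counting (those regions
    are ignored, not wrong).  Precision with zero predictions is 1.0
    (no false claims).  Default thresholds: 101 evenly spaced score
    quantiles of the pooled candidate scores.

    Returns a list of dicts with keys threshold/precision/recall/tp/fp/fn.
    """
    if not scenes or not any(s.faces for s in scenes):
        raise ValueError("evaluation requires scenes with annotations")
    per_scene = []
    n_truth = 0
    for scene in scenes:
        image = _scene_image(scene, images)
        dets = detect(model, image, threshold=-np.inf)
        dets = [d for d in dets
                if not any((not f.valid) and iou(d.box, f.box) > 0.3
                           for f in scene.faces)]
        truths = [f.box for f in scene.valid_faces]
        n_truth += len(truths)
        matches = []  # (score, matched?)
        used = [False] * len(truths)
        for det in sorted(dets, key=lambda d: -d.score):
            best, best_iou = -1, 0.5
            for ti, tb in enumerate(truths):
                if used[ti]:
                    continue
                o = iou(det.box, tb)
                if o >= best_iou:
                    best, best_iou = ti, o
            if best >= 0:
                used[best] = True
                matches.append((det.score, True))
            else:
                matches.append((det.score, False))
        per_scene.append(matches)
    all_scores = np.array([s for m in per_scene for (s, _) in m])
    if thresholds is None:
        if all_scores.size:
            thresholds = list(np.quantile(all_scores, np.linspace(0, 1, 101)))
        else:
            thresholds = [0.0]
    rows = []
    for thr in thresholds:
        tp = fp = 0
        for matches in per_scene:
            for score, matched in matches:
                if score >= thr:
                    tp += matched
                    fp += not matched
        fn = n_truth - tp
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / n_truth if n_truth else 0.0
        rows.append({"threshold": float(thr), "precision": precision,
                     "recall": recall, "tp": tp, "fp": fp, "fn": fn})
    return rows


def stratified_kfold(items: list, strata: list, k: int, seed: int = 0
                     ) -> list[tuple[list[int], list[int]]]:
    """Split items into k folds, stratum by stratum.

    Each stratum is shuffled and cut into k sections whose sizes differ
    by at most one; fold f validates on section f of every stratum.
    Strata smaller than k are distributed round-robin with a warning.
    Returns k (train_indices, validation_indices) pairs.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(items) != len(strata):
        raise ValueError("items and strata must have equal length")
    rng = np.random.default_rng(seed)
    sections: list[list[int]] = [[] for _ in range(k)]
    order = {}
    for idx, stratum in enumerate(strata):
        order.setdefault(stratum, []).append(idx)
    for stratum in sorted(order, key=str):
        idxs = np.array(order[stratum])
        if len(idxs) < k:
            warnings.warn(
                f"stratum {stratum!r} has {len(idxs)} items < k={k}; "
                "distributing round-robin")
        perm = idxs[rng.permutation(len(idxs))]
        for j, idx in enumerate(perm):
            sections[j % k].append(int(idx))
    folds = []
    for f in range(k):
        val = sorted(sections[f])
        train = sorted(i for j in range(k) if j != f for i in sections[j])
        folds.append((train, val))
    return folds


def save_detector(model: DetectorModel, path) -> None:
    import json
    arrays = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8), **arrays)


def load_detector(path) -> DetectorModel:
    import json
    with np.load(path) as data:
        cfg_raw = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_raw)
        cfg_dict["detection_window"] = tuple(cfg_dict["detection_window"])
        model = DetectorModel(DetectorConfig(**cfg_dict))
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    state = model.state_arrays()
    for k, v in arrays.items():
        state[k][...] = v
    return model
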