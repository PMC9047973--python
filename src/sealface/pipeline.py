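"""End-to-end orchestration: generate -> detect -> chip -> embed -> identify.

One root seed drives every stage through named substreams, so a rerun
with the same configuration reproduces the same report and any stage
can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path
import zlib

import numpy as np
import yaml

from . import detection, identification, recognition, synth
from .alignment import ChipGeometry, EyePair, align_and_chip
from .annotations import (load_chip_folders, load_image, read_annotations,
                          save_chip)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_reference_numbers",
           "stage_seed", "chip_scenes"]

#: Published reference metrics from the original Casco Bay field study
#: (photographs available only on request; these numbers are reported
#: for context and are not reproduced by this package's synthetic runs).
REFERENCE_METRICS = [
    {"metric": "detector precision", "value": 85.43, "unit": "%"},
    {"metric": "detector recall", "value": 86.94, "unit": "%"},
    {"metric": "closed-set rank-1 accuracy", "value": 88.0, "unit": "%"},
    {"metric": "closed-set rank-5 accuracy", "value": 96.0, "unit": "%"},
    {"metric": "open-set rank-1 TPR", "value": 0.678, "unit": "fraction"},
    {"metric": "open-set rank-1 FPR", "value": 0.032, "unit": "fraction"},
    {"metric": "open-set rank-1 accuracy", "value": 0.945, "unit": "fraction"},
    {"metric": "open-set rank-1 F-score", "value": 0.663, "unit": "fraction"},
    {"metric": "match similarity (same individual)", "value": 0.65,
     "unit": "cosine"},
]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (root_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_run"
    seed: int = 0
    # data generation
    identities: int = 20
    chips_per_identity: int = 6
    scenes: int = 24
    faces_per_scene: int = 4
    scene_size: tuple[int, int] = (320, 320)
    difficulty: float = 0.0
    invalid_fraction: float = 0.1
    # stage configs
    detector: detection.DetectorConfig = field(
        default_factory=detection.DetectorConfig)
    embedder: recognition.EmbedderConfig = field(
        default_factory=recognition.EmbedderConfig)
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    # evaluation
    k_folds: int = 5
    protocol: str = "closed"
    open_set_threshold: float = 0.5
    holdout_scene_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "detector":
                kwargs[key] = detection.DetectorConfig(**value)
            elif key == "embedder":
                value = dict(value)
                for tup in ("channels", "groups"):
                    if tup in value:
                        value[tup] = tuple(value[tup])
                kwargs[key] = recognition.EmbedderConfig(**value)
            elif key == "geometry":
                kwargs[key] = ChipGeometry(**value)
            elif key == "scene_size":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def chip_scenes(scenes, geometry: ChipGeometry | None = None,
                out_dir=None, images=None):
    """Cut aligned chips for every valid annotated face.

    Returns chips grouped by identity; writes one-folder-per-individual
    PNGs when ``out_dir`` is given.
    """
    geometry = geometry or ChipGeometry()
    chips_by_identity: dict[str, list] = {}
    skipped = 0
    for scene in scenes:
        image = (images[scene.image_path] if images is not None
                 else load_image(scene.image_path))
        for face in scene.faces:
            if not face.valid:
                skipped += 1
                continue
            chip = align_and_chip(
                image, EyePair(left=face.left_eye, right=face.right_eye),
                geometry, source_image=scene.image_path, source_box=face.box)
            chip.identity = face.identity
            key = face.identity if face.identity is not None else "unknown"
            chips_by_identity.setdefault(key, []).append(chip)
    if skipped:
        logger.info("chipping skipped %d invalid-flagged faces", skipped)
    if out_dir is not None:
        for identity, chips in chips_by_identity.items():
            for chip in chips:
                save_chip(chip, Path(out_dir) / identity)
    return chips_by_identity


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return a machine-readable report.

    Stages: synthetic data generation, detector training + held-out
    precision/recall, chipping, embedder cross-validation (closed or
    open protocol), and a gallery-growth pass enrolling each identity's
    chips probe-by-probe.  Any stage failure raises with the stage name.
    """
    report: dict = {"config_digest": _digest(config), "stages": {}}
    stage = "generate"
    try:
        if config.identities < 1:
            raise ValueError("pipeline needs at least one identity")
        out = Path(config.out_dir)
        dataset = synth.generate_dataset(synth.DatasetConfig(
            identities=config.identities,
            chips_per_identity=config.chips_per_identity,
            scenes=config.scenes, faces_per_scene=config.faces_per_scene,
            scene_size=config.scene_size,
            seed=stage_seed(config.seed, "generate"),
            out_dir=str(out / "data"), overwrite=True,
            difficulty=config.difficulty,
            invalid_fraction=config.invalid_fraction,
            chip_geometry=config.geometry))
        scenes = read_annotations(dataset / "annotations.json",
                                  base_dir=dataset)
        report["stages"][stage] = {
            "scenes": len(scenes),
            "faces": sum(len(s.faces) for s in scenes),
            "valid_faces": sum(len(s.valid_faces) for s in scenes),
        }

        stage = "train-detect"
        n_holdout = max(1, int(len(scenes) * config.holdout_scene_fraction))
        train_scenes, val_scenes = scenes[n_holdout:], scenes[:n_holdout]
        det_cfg = detection.DetectorConfig(
            **{**asdict(config.detector),
               "seed": stage_seed(config.seed, "detector")})
        det_cfg.detection_window = tuple(det_cfg.detection_window)
        detector = detection.build_detector(det_cfg)
        detector, det_losses = detection.train_detector(
            detector, train_scenes, det_cfg)
        detection.save_detector(detector, out / "detector.npz")
        report["stages"][stage] = {
            "epochs": det_cfg.epochs,
            "initial_loss": det_losses[0] if det_losses else None,
            "final_loss": det_losses[-1] if det_losses else None,
        }

        stage = "eval-detect"
        pr = detection.evaluate_detector(detector, val_scenes)
        at_default = min(pr, key=lambda r: abs(r["threshold"]
                                               - det_cfg.threshold))
        best = max(pr, key=lambda r: min(r["precision"], r["recall"]))
        report["stages"][stage] = {
            "precision_at_default": at_default["precision"],
            "recall_at_default": at_default["recall"],
            "best_threshold": best["threshold"],
            "best_precision": best["precision"],
            "best_recall": best["recall"],
        }

        stage = "chip"
        chips = chip_scenes(scenes, config.geometry,
                            out_dir=out / "scene_chips")
        report["stages"][stage] = {
            "individuals": len(chips),
            "chips": sum(len(v) for v in chips.values()),
        }

        stage = "train-embed"
        chips_by_identity = load_chip_folders(dataset / "chips")
        emb_cfg = recognition.EmbedderConfig(
            **{**asdict(config.embedder),
               "seed": stage_seed(config.seed, "embedder")})
        emb_cfg.channels = tuple(emb_cfg.channels)
        emb_cfg.groups = tuple(emb_cfg.groups)

        def train_fn(train_chips, seed):
            cfg = recognition.EmbedderConfig(
                **{**asdict(emb_cfg), "seed": seed,
                   "channels": emb_cfg.channels, "groups": emb_cfg.groups})
            model = recognition.build_embedder(cfg)
            recognition.train_embedder(model, train_chips, cfg)
            return lambda c: recognition.embed_chips(model, c)

        cv = identification.cross_validate(
            chips_by_identity, k_folds=config.k_folds,
            protocol=config.protocol,
            seed=stage_seed(config.seed, "cross-validate"),
            train_fn=train_fn, threshold=config.open_set_threshold)
        report["stages"][stage] = {"mean": cv["mean"], "sd": cv["sd"]}

        stage = "enroll-probe"
        embed_fn = train_fn(chips_by_identity,
                            stage_seed(config.seed, "enroll"))
        gallery = identification.Gallery()
        decisions = {"new": 0, "merge": 0, "correct_merge": 0}
        half = {i: c[:max(1, len(c) // 2)] for i, c in chips_by_identity.items()}
        rest = {i: c[max(1, len(c) // 2):] for i, c in chips_by_identity.items()}
        enrolled = {}
        for identity in sorted(half):
            gid = gallery.next_id()
            gallery.enroll(gid, embed_fn(half[identity]))
            enrolled[identity] = gid
        for identity in sorted(rest):
            if not rest[identity]:
                continue
            gallery, decision = identification.enroll_or_merge(
                gallery, embed_fn(rest[identity]),
                threshold=config.open_set_threshold)
            decisions[decision["decision"]] += 1
            if (decision["decision"] == "merge"
                    and decision["identity"] == enrolled[identity]):
                decisions["correct_merge"] += 1
        report["stages"][stage] = {"gallery_size": len(gallery), **decisions}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["report_digest"] = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=float).encode()).hexdigest()
    (Path(config.out_dir) / "report.json").write_text(
        json.dumps(report, indent=1, default=float))
    return report


def _digest(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir", None)  # digest covers the science, not the paths
    return hashlib.sha256(json.dumps(
        payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def report_reference_numbers(current: dict | None = None) -> list[dict]:
    """The published reference metrics, optionally joined with a run.

    ``current`` may map metric names to this run's values; missing
    entries print as "-".  The published values come from the original
    field study whose photographs are not redistributable, so they are
    context, not a reproduction target.
    """
    rows = []
    for entry in REFERENCE_METRICS:
        row = dict(entry)
        row["label"] = "reference (original data, not reproducible here)"
        row["current"] = (current or {}).get(entry["metric"], "-")
        rows.append(row)
    return rows
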