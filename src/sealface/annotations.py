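"""Annotation and chip-folder I/O.

Scene annotations (face boxes, eye landmarks, validity flags, optional
ground-truth identities) are stored in a single JSON file per dataset.
imglab-style XML datasets can be imported (read-only).  Chips are
stored one folder per individual; a chip's filename encodes where in
which source image it was cut from, so provenance survives the
file system round-trip.

Conventions
-----------
* Coordinates are 0-based pixels, x right, y down.
* Boxes are (left, top, width, height), half-open.
* "Left eye" is the eye with the smaller x coordinate (viewer's left).

JSON schema (version 1)::

    {"format": "sealface-annotations", "version": 1,
     "scenes": [{"image_path": str, "image_size": [H, W],
                 "stratum": str,
                 "faces": [{"box": [l, t, w, h],
                            "left_eye": [x, y], "right_eye": [x, y],
                            "valid": bool, "identity": str | null}]}]}
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path
import re
import xml.etree.ElementTree as ET

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "FaceAnnotation",
    "AnnotatedScene",
    "ChipRecord",
    "write_annotations",
    "read_annotations",
    "read_imglab_xml",
    "encode_chip_name",
    "decode_chip_name",
    "load_chip_folders",
    "save_chip",
    "load_image",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class FaceAnnotation:
    box: tuple[int, int, int, int]  # (left, top, width, height)
    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    valid: bool = True
    identity: str | None = None

    def __post_init__(self):
        l, t, w, h = self.box
        if w <= 0 or h <= 0:
            raise ValueError(f"face box must have positive size, got {self.box}")
        if tuple(self.left_eye) == tuple(self.right_eye):
            raise ValueError("eye landmarks must be distinct")
        if self.valid:
            for x, y in (self.left_eye, self.right_eye):
                if not (l <= x < l + w and t <= y < t + h):
                    raise ValueError(
                        f"eye ({x}, {y}) outside box {self.box} on a valid face")


@dataclass
class AnnotatedScene:
    image_path: str
    image_size: tuple[int, int]  # (H, W)
    faces: list[FaceAnnotation] = field(default_factory=list)
    stratum: str = ""

    def __post_init__(self):
        h, w = self.image_size
        for f in self.faces:
            l, t, bw, bh = f.box
            if l < 0 or t < 0 or l + bw > w or t + bh > h:
                raise ValueError(
                    f"box {f.box} outside image bounds {w}x{h}")

    @property
    def valid_faces(self) -> list[FaceAnnotation]:
        return [f for f in self.faces if f.valid]


@dataclass
class ChipRecord:
    """A canonical 112x112 grayscale face chip with provenance."""

    pixels: np.ndarray
    source_image: str
    source_box: tuple[int, int, int, int]
    identity: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not self.source_image:
            raise ValueError("chip provenance requires a source image name")


def _face_to_json(f: FaceAnnotation) -> dict:
    return {"box": list(f.box),
            "left_eye": list(f.left_eye), "right_eye": list(f.right_eye),
            "valid": f.valid, "identity": f.identity}


def _face_from_json(d: dict) -> FaceAnnotation:
    return FaceAnnotation(box=tuple(d["box"]),
                          left_eye=tuple(d["left_eye"]),
                          right_eye=tuple(d["right_eye"]),
                          valid=bool(d["valid"]),
                          identity=d.get("identity"))


def write_annotations(scenes: list[AnnotatedScene], path) -> None:
    """Write scene annotations as JSON; lossless against read_annotations."""
    doc = {"format": "sealface-annotations", "version": 1,
           "scenes": [{"image_path": s.image_path,
                       "image_size": list(s.image_size),
                       "stratum": s.stratum,
                       "faces": [_face_to_json(f) for f in s.faces]}
                      for s in scenes]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations(path, base_dir=None) -> list[AnnotatedScene]:
    """Read scene annotations.

    ``base_dir``: resolve relative image paths against this directory
    (annotation files written by the dataset generator store paths
    relative to the dataset root, keeping the tree relocatable).
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "sealface-annotations":
        raise ValueError(f"{path}: not a sealface annotation file")

    def resolve(p: str) -> str:
        if base_dir is not None and not Path(p).is_absolute():
            return str(Path(base_dir) / p)
        return p

    return [AnnotatedScene(image_path=resolve(s["image_path"]),
                           image_size=tuple(s["image_size"]),
                           faces=[_face_from_json(f) for f in s["faces"]],
                           stratum=s.get("stratum", ""))
            for s in doc["scenes"]]


def read_imglab_xml(path) -> list[AnnotatedScene]:
    """Import an imglab dataset XML file.

    Dialect: ``<dataset><images><image file=...><box top= left= width=
    height= [ignore=...]> [<part name=... x= y=/>] ...``.  Boxes with an
    ``ignore`` attribute map to ``valid=False``.  Eye landmarks are
    parts named ``leye``/``reye`` (or ``left_eye``/``right_eye``); boxes
    without both eye parts get eye positions estimated at the canonical
    in-box locations (0.3/0.7 of width, 0.4 of height), flagged valid
    per the box.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValueError(f"{path}: malformed XML at line {line}, column {col}") from exc
    scenes = []
    for image_el in tree.getroot().iter("image"):
        file_attr = image_el.get("file", "")
        faces = []
        for box_el in image_el.findall("box"):
            l = int(box_el.get("left"))
            t = int(box_el.get("top"))
            w = int(box_el.get("width"))
            h = int(box_el.get("height"))
            valid = box_el.get("ignore") is None
            parts = {p.get("name"): (float(p.get("x")), float(p.get("y")))
                     for p in box_el.findall("part")}
            left = parts.get("leye") or parts.get("left_eye")
            right = parts.get("reye") or parts.get("right_eye")
            if left is None or right is None:
                left = (l + 0.3 * w, t + 0.4 * h)
                right = (l + 0.7 * w, t + 0.4 * h)
            faces.append(FaceAnnotation(box=(l, t, w, h), left_eye=left,
                                        right_eye=right, valid=valid))
        # imglab files carry no image dimensions; use a bound that
        # satisfies the in-bounds invariant
        max_w = max((f.box[0] + f.box[2] for f in faces), default=1)
        max_h = max((f.box[1] + f.box[3] for f in faces), default=1)
        scenes.append(AnnotatedScene(image_path=file_attr,
                                     image_size=(max_h, max_w), faces=faces))
    return scenes


_CHIP_NAME_RE = re.compile(
    r"^(?P<stem>.+)_l(?P<l>-?\d+)_t(?P<t>-?\d+)_w(?P<w>\d+)_h(?P<h>\d+)\.png$")


def encode_chip_name(source_image: str, box) -> str:
    """Filesystem-safe chip filename encoding source image and box."""
    l, t, w, h = (int(v) for v in box)
    stem = Path(source_image).name
    stem = Path(stem).stem
    stem = re.sub(r"[^A-Za-z0-9._-]", "-", stem)
    return f"{stem}_l{l}_t{t}_w{w}_h{h}.png"


def decode_chip_name(name: str) -> tuple[str, tuple[int, int, int, int]]:
    m = _CHIP_NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot decode chip provenance from {name!r}")
    return m.group("stem"), (int(m.group("l")), int(m.group("t")),
                             int(m.group("w")), int(m.group("h")))


def save_chip(chip: ChipRecord, directory) -> Path:
    """Write a chip PNG into ``directory`` using the provenance filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = encode_chip_name(chip.source_image, chip.source_box)
    path = directory / name
    Image.fromarray(chip.pixels.astype(np.uint8), mode="L").save(path)
    return path


def load_image(path) -> np.ndarray:
    """Load an image file as a grayscale uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def load_chip_folders(root_dir) -> dict[str, list[ChipRecord]]:
    """Load chips grouped one-folder-per-individual.

    Identity keys are the subdirectory names, preserved verbatim (the
    convention is a zero-padded number plus optional nickname, e.g.
    ``015_Armani``).  Ordering is deterministic (sorted names).  Chip
    provenance is decoded from filenames when possible; otherwise the
    filename itself becomes the source record.
    """
    root = Path(root_dir)
    out: dict[str, list[ChipRecord]] = {}
    subdirs = sorted(p for p in root.iterdir() if p.is_dir()) if root.is_dir() else []
    if not subdirs:
        logger.warning("no individual folders found under %s", root)
        return out
    for sub in subdirs:
        chips = []
        for f in sorted(sub.iterdir()):
            if not f.is_file():
                continue
            if f.suffix.lower() not in IMAGE_SUFFIXES:
                logger.info("skipping non-image file %s", f)
                continue
            try:
                source, box = decode_chip_name(f.name)
            except ValueError:
                source, box = f.name, (0, 0, 1, 1)
            chips.append(ChipRecord(pixels=load_image(f), source_image=source,
                                    source_box=box, identity=sub.name))
        if not chips:
            logger.warning("individual folder %s contains no chips", sub)
        out[sub.name] = chips
    return out
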