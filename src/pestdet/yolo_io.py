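"""YOLO-format dataset plumbing.

Plain-text label files (one ``class cx cy w h`` row per object, normalized
center-size fractions), 70/20/10 train/val/test splitting, letterboxing to
the square working size, and the YAML dataset config that names classes and
split directories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .boxes import NormBox

PAD_GRAY = 114  # letterbox fill value per channel


class LabelParseError(ValueError):
    """Raised for malformed label lines; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"label line {line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True)
class LabeledImage:
    """An 8-bit RGB image with its ordered list of normalized boxes."""

    pixels: np.ndarray  # H x W x 3 uint8
    boxes: list[NormBox]
    identifier: str


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test identifier lists."""

    train: list[str]
    val: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def __iter__(self):
        yield from (self.train, self.val, self.test)


def read_yolo_labels(text: str, num_classes: int) -> list[NormBox]:
    """Parse label-file contents into validated boxes, order preserved.

    Raises :class:`LabelParseError` naming the offending line for malformed
    rows and ``ValueError`` for out-of-range class ids or coordinates.
    """
    boxes: list[NormBox] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(line_no, f"expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:])
        except ValueError as exc:
            raise LabelParseError(line_no, str(exc)) from exc
        boxes.append(NormBox(cls, cx, cy, w, h).validate(num_classes))
    return boxes


def write_yolo_labels(boxes: list[NormBox]) -> str:
    """Serialize boxes at fixed 6-decimal precision; inverse of
    :func:`read_yolo_labels` at that precision."""
    lines = []
    for b in boxes:
        b.validate()
        lines.append(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def split_dataset(ids: list[str],
                  fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0, *,
                  labels: dict[str, int] | None = None) -> DatasetSplit:
    """Deterministic shuffled split with floor allocation.

    ``|train| = floor(f_train * N)``, ``|val| = floor(f_val * N)``, test takes
    the remainder.  The assignment depends only on the identifier *set* and
    the seed, not on input order.  With ``labels`` (identifier -> class id)
    the floor rule is applied per class (stratified split).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 identifiers to split, got {n}")
    if len(set(ids)) != n:
        raise ValueError("identifiers must be unique")

    def allocate(pool: list[str], rng: np.random.Generator):
        pool = sorted(pool)  # order-independence: canonicalize before shuffling
        perm = rng.permutation(len(pool))
        shuffled = [pool[i] for i in perm]
        n_train = int(np.floor(fractions[0] * len(pool)))
        n_val = int(np.floor(fractions[1] * len(pool)))
        return (shuffled[:n_train], shuffled[n_train:n_train + n_val],
                shuffled[n_train + n_val:])

    rng = np.random.default_rng(seed)
    if labels is None:
        train, val, test = allocate(list(ids), rng)
    else:
        train, val, test = [], [], []
        for cls in sorted({labels[i] for i in ids}):
            tr, va, te = allocate([i for i in ids if labels[i] == cls], rng)
            train += tr
            val += va
            test += te
    if not test:
        raise ValueError("test split is empty; provide more identifiers")
    return DatasetSplit(train, val, test, tuple(fractions))


@dataclass(frozen=True)
class LetterboxTransform:
    """Affine record mapping original pixel coordinates to the letterboxed
    frame: ``x' = x * scale + pad_x``, ``y' = y * scale + pad_y``."""

    scale: float
    pad_x: float
    pad_y: float
    original_size: tuple[int, int]  # (width, height)
    target: int

    def apply_xyxy(self, box: np.ndarray) -> np.ndarray:
        box = np.asarray(box, dtype=np.float64)
        out = box * self.scale
        out[..., [0, 2]] += self.pad_x
        out[..., [1, 3]] += self.pad_y
        return out

    def invert_xyxy(self, box: np.ndarray) -> np.ndarray:
        box = np.asarray(box, dtype=np.float64).copy()
        box[..., [0, 2]] -= self.pad_x
        box[..., [1, 3]] -= self.pad_y
        return box / self.scale


def letterbox(image: np.ndarray, target: int = 512
              ) -> tuple[np.ndarray, LetterboxTransform]:
    """Resize preserving aspect ratio and pad with gray to ``target`` square.

    Returns the padded image and the coordinate transform; forward/inverse
    coordinate maps are exact inverses on the image region.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    scale = min(target / w, target / h)
    new_w, new_h = round(w * scale), round(h * scale)
    if (new_w, new_h) != (w, h):
        resized = np.asarray(
            Image.fromarray(image.astype(np.uint8)).resize(
                (new_w, new_h), Image.BILINEAR))
    else:
        resized = image.astype(np.uint8)
    out = np.full((target, target, 3), PAD_GRAY, dtype=np.uint8)
    pad_x = (target - new_w) // 2
    pad_y = (target - new_h) // 2
    out[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = resized
    return out, LetterboxTransform(scale, float(pad_x), float(pad_y), (w, h), target)


# -- dataset directories -------------------------------------------------------

@dataclass
class DatasetConfig:
    """Class names plus image/label directories, as stored in data.yaml."""

    names: list[str]
    root: Path
    images_dir: str = "images"
    labels_dir: str = "labels"
    splits: dict[str, list[str]] = field(default_factory=dict)

    @property
    def num_classes(self) -> int:
        return len(self.names)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls(names=list(raw["names"]), root=path.parent,
                   images_dir=raw.get("images_dir", "images"),
                   labels_dir=raw.get("labels_dir", "labels"),
                   splits={k: list(v) for k, v in raw.get("splits", {}).items()})

    def save(self, path: str | Path):
        payload = {"names": self.names, "images_dir": self.images_dir,
                   "labels_dir": self.labels_dir, "splits": self.splits}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    def load_image(self, identifier: str) -> LabeledImage:
        img_path = self.root / self.images_dir / f"{identifier}.png"
        if not img_path.exists():
            img_path = img_path.with_suffix(".jpg")
        pixels = np.asarray(Image.open(img_path).convert("RGB"))
        label_path = self.root / self.labels_dir / f"{identifier}.txt"
        text = label_path.read_text() if label_path.exists() else ""
        return LabeledImage(pixels, read_yolo_labels(text, self.num_classes),
                            identifier)

    def load_split(self, split: str) -> list[LabeledImage]:
        return [self.load_image(i) for i in self.splits[split]]


def save_labeled_image(sample: LabeledImage, root: str | Path,
                       images_dir: str = "images", labels_dir: str = "labels"):
    root = Path(root)
    (root / images_dir).mkdir(parents=True, exist_ok=True)
    (root / labels_dir).mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.pixels).save(root / images_dir / f"{sample.identifier}.png")
    (root / labels_dir / f"{sample.identifier}.txt").write_text(
        write_yolo_labels(sample.boxes))


def write_manifest(path: str | Path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
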