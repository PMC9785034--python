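"""Bounding-box primitives shared across the package.

Conventions: normalized boxes are YOLO center-size fractions of the image
side; pixel boxes are 0-based, corner-inclusive ``(x1, y1, x2, y2)``
("xyxy").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NormBox:
    """One normalized ground-truth box: class id plus YOLO center/size
    fractions.  ``cx, cy`` in [0, 1]; ``w, h`` in (0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self, num_classes: int | None = None) -> "NormBox":
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center outside [0,1]: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size outside (0,1]: ({self.w}, {self.h})")
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")
        if num_classes is not None and self.class_id >= num_classes:
            raise ValueError(
                f"class id {self.class_id} out of range for {num_classes} classes")
        return self

    def to_xyxy(self, width: int, height: int) -> np.ndarray:
        """Denormalize to pixel xyxy, clamped to the image."""
        x1 = (self.cx - self.w / 2.0) * width
        y1 = (self.cy - self.h / 2.0) * height
        x2 = (self.cx + self.w / 2.0) * width
        y2 = (self.cy + self.h / 2.0) * height
        return np.array([max(x1, 0.0), max(y1, 0.0),
                         min(x2, float(width)), min(y2, float(height))],
                        dtype=np.float64)


@dataclass(frozen=True)
class Detection:
    """One decoded detection: class id, confidence in [0, 1], pixel xyxy box."""

    class_id: int
    score: float
    box: tuple[float, float, float, float]

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate detection box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score outside [0,1]: {self.score}")


def boxes_to_array(boxes: list[NormBox]) -> np.ndarray:
    """(N, 5) array of [class, cx, cy, w, h]."""
    if not boxes:
        return np.zeros((0, 5), dtype=np.float64)
    return np.array([[b.class_id, b.cx, b.cy, b.w, b.h] for b in boxes],
                    dtype=np.float64)


def xywhn_to_xyxy(arr: np.ndarray, width: float, height: float) -> np.ndarray:
    """Vectorized center-size fractions -> pixel xyxy (no clamping)."""
    out = np.empty_like(arr, dtype=np.float64)
    out[..., 0] = (arr[..., 0] - arr[..., 2] / 2) * width
    out[..., 1] = (arr[..., 1] - arr[..., 3] / 2) * height
    out[..., 2] = (arr[..., 0] + arr[..., 2] / 2) * width
    out[..., 3] = (arr[..., 1] + arr[..., 3] / 2) * height
    return out


def iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) xyxy boxes -> (N, M)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def iou_wh(wh_a: np.ndarray, wh_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of width-height pairs assuming shared top-left corner —
    the distance kernel of anchor clustering."""
    wh_a = np.atleast_2d(np.asarray(wh_a, dtype=np.float64))
    wh_b = np.atleast_2d(np.asarray(wh_b, dtype=np.float64))
    inter = (np.minimum(wh_a[:, None, 0], wh_b[None, :, 0])
             * np.minimum(wh_a[:, None, 1], wh_b[None, :, 1]))
    union = (wh_a[:, 0] * wh_a[:, 1])[:, None] + \
            (wh_b[:, 0] * wh_b[:, 1])[None, :] - inter
    return inter / np.maximum(union, 1e-12)
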