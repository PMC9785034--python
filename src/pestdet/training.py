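"""Training loop and run artifacts.

One epoch: augment (horizontal flip, scale jitter), forward, composite
loss, SGD step; after each epoch the model is scored on the validation
split and the weights with the best mAP@0.5 across the run are retained.
SGD uses momentum with weight decay applied to convolution and linear
weights only; the learning rate warms up linearly over the first
iterations and then follows a cosine schedule.  Anchors are recomputed
from the training labels by default.  Runs are deterministic under the
configured seed.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .boxes import Detection, NormBox
from .layers import BatchNorm, Conv2d, Linear
from .losses import DEFAULT_GAINS, assign_batch, compute_loss
from .metrics import EvalReport, evaluate_detections
from .network import (Detector, anchors_from_labels, decode, forward, nms,
                      preprocess, save_checkpoint)
from .yolo_io import LabeledImage


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 10
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    final_lr_fraction: float = 0.1
    warmup_iters: int = 50
    seed: int = 0
    hflip: bool = True
    scale_jitter: bool = True
    jitter_range: tuple[float, float] = (0.8, 1.2)
    recompute_anchors: bool = True
    bn_freeze_fraction: float | None = 0.25
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    eval_conf_thresh: float = 0.001
    eval_iou_thresh: float = 0.5
    nms_iou_thresh: float = 0.45

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainResult:
    best_state: dict
    best_map: float
    best_epoch: int
    history: list[dict]
    final_eval: EvalReport | None = None


class SGD:
    """Momentum SGD with decoupled parameter groups (weight decay on
    conv/linear weights only, the usual convention for BN networks) and
    global gradient-norm clipping."""

    def __init__(self, model: Detector, lr: float, momentum: float,
                 weight_decay: float, max_grad_norm: float = 10.0):
        self.lr, self.momentum = lr, momentum
        self.max_grad_norm = max_grad_norm
        self.groups = []
        for m in model.modules():
            for name, p in m._params.items():
                decay = (weight_decay
                         if isinstance(m, (Conv2d, Linear)) and name == "weight"
                         else 0.0)
                self.groups.append((p, decay, np.zeros_like(p.data)))

    def step(self):
        if self.max_grad_norm is not None:
            sq = sum(float((p.grad.astype(np.float64) ** 2).sum())
                     for p, _, _ in self.groups if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / (norm + 1e-12)
                for p, _, _ in self.groups:
                    if p.grad is not None:
                        p.grad *= scale
        for p, decay, buf in self.groups:
            if p.grad is None:
                continue
            g = p.grad + decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self):
        for p, _, _ in self.groups:
            p.zero_grad()


def _augment(image: np.ndarray, boxes: list[NormBox],
             rng: np.random.Generator, cfg: TrainConfig
             ) -> tuple[np.ndarray, list[NormBox]]:
    """Horizontal flip and center scale jitter on one uint8 HWC sample."""
    size = image.shape[0]
    if cfg.hflip and rng.random() < 0.5:
        image = image[:, ::-1]
        boxes = [NormBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in boxes]
    if cfg.scale_jitter:
        s = rng.uniform(*cfg.jitter_range)
        if abs(s - 1.0) > 1e-3:
            from PIL import Image as PILImage

            new = max(32, int(round(size * s)))
            resized = np.asarray(PILImage.fromarray(image).resize(
                (new, new), PILImage.BILINEAR))
            canvas = np.full_like(image, 114)
            if new <= size:  # zoom out: center-pad
                off = (size - new) // 2
                canvas[off:off + new, off:off + new] = resized
                scale, shift = new / size, off / size
            else:  # zoom in: center-crop
                off = (new - size) // 2
                canvas = resized[off:off + size, off:off + size]
                scale, shift = new / size, -off / size
            out_boxes = []
            for b in boxes:
                cx = b.cx * scale + shift
                cy = b.cy * scale + shift
                w, h = b.w * scale, b.h * scale
                x1, y1 = np.clip([cx - w / 2, cy - h / 2], 0.0, 1.0)
                x2, y2 = np.clip([cx + w / 2, cy + h / 2], 0.0, 1.0)
                if (x2 - x1) * size >= 2 and (y2 - y1) * size >= 2:
                    out_boxes.append(NormBox(b.class_id, (x1 + x2) / 2,
                                             (y1 + y2) / 2, x2 - x1, y2 - y1))
            image, boxes = canvas, out_boxes
    return np.ascontiguousarray(image), boxes


def predict_dataset(model: Detector, samples: list[LabeledImage],
                    conf_thresh: float = 0.001, nms_iou: float = 0.45,
                    batch_size: int = 8) -> list[list[Detection]]:
    """Decoded, NMS-filtered detections per sample (samples already at the
    working size)."""
    model.eval()
    out: list[list[Detection]] = []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        batch = np.stack([preprocess(s.pixels) for s in chunk])
        raw = forward(model, batch)
        for b in range(len(chunk)):
            dets = decode([r[b] for r in raw], model.spec, conf_thresh)
            out.append(nms(dets, nms_iou))
    return out


def evaluate_model(model: Detector, samples: list[LabeledImage],
                   conf_thresh: float = 0.001, iou_thresh: float = 0.5,
                   nms_iou: float = 0.45) -> EvalReport:
    """mAP@0.5-style report of a model on labeled samples."""
    dets = predict_dataset(model, samples, conf_thresh, nms_iou)
    size = samples[0].pixels.shape[0] if samples else model.spec.input_size
    gts = [[(b.class_id, b.to_xyxy(size, size)) for b in s.boxes]
           for s in samples]
    return evaluate_detections(dets, gts, model.spec.num_classes, iou_thresh)


def train(model: Detector, train_samples: list[LabeledImage],
          val_samples: list[LabeledImage], config: TrainConfig) -> TrainResult:
    """Run the epoch loop and return the best-mAP checkpoint and history.

    Samples must already be letterboxed to a square size divisible by 32;
    the model's anchor table is refit to the training labels unless
    ``config.recompute_anchors`` is off.  A non-finite loss aborts with
    diagnostics.
    """
    if not train_samples or not val_samples:
        raise ValueError("need nonempty train and val sets")
    size = train_samples[0].pixels.shape[0]
    if size % 32:
        raise ValueError(f"sample size {size} not divisible by 32")
    rng = np.random.default_rng(config.seed)

    if config.recompute_anchors:
        anchors = anchors_from_labels(train_samples, size,
                                      model.spec.num_scales)
        model.spec = model.spec.with_anchors(anchors)

    opt = SGD(model, config.lr, config.momentum, config.weight_decay)
    iters_per_epoch = max(1, int(np.ceil(len(train_samples) / config.batch_size)))
    total_iters = config.epochs * iters_per_epoch

    freeze_epoch = (None if config.bn_freeze_fraction is None else
                    int(round(config.bn_freeze_fraction * config.epochs)))

    history: list[dict] = []
    best_state, best_map, best_epoch = None, -1.0, -1
    it = 0
    for epoch in range(config.epochs):
        if freeze_epoch is not None and epoch == freeze_epoch:
            model.freeze_bn_stats()
        model.train()
        order = rng.permutation(len(train_samples))
        sums = np.zeros(4)
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            imgs, labels = [], []
            for i in idx:
                s = train_samples[i]
                img, boxes = _augment(s.pixels, s.boxes, rng, config)
                imgs.append(preprocess(img))
                labels.append(boxes)
            # schedule: linear warmup then cosine decay to the final fraction
            if it < config.warmup_iters:
                opt.lr = config.lr * (it + 1) / config.warmup_iters
            else:
                frac = (it - config.warmup_iters) / max(
                    1, total_iters - config.warmup_iters)
                cos = 0.5 * (1 + np.cos(np.pi * frac))
                opt.lr = config.lr * (
                    config.final_lr_fraction + (1 - config.final_lr_fraction) * cos)
            raw = model.raw_tensors(Tensor(np.stack(imgs)))
            assignment = assign_batch(labels, model.spec, size)
            report = compute_loss(raw, assignment, model.spec,
                                  config.gains, size)
            if not np.isfinite(report.total):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch} iter {it}: "
                    f"box={report.loss_box} obj={report.loss_object} "
                    f"cls={report.loss_class} lr={opt.lr}")
            opt.zero_grad()
            report.total_tensor.backward()
            opt.step()
            sums += (report.loss_box, report.loss_object,
                     report.loss_class, report.total)
            it += 1
        ev = evaluate_model(model, val_samples, config.eval_conf_thresh,
                            config.eval_iou_thresh, config.nms_iou_thresh)
        n_batches = int(np.ceil(len(order) / config.batch_size))
        row = dict(epoch=epoch, loss_box=sums[0] / n_batches,
                   loss_obj=sums[1] / n_batches, loss_cls=sums[2] / n_batches,
                   loss_total=sums[3] / n_batches,
                   precision=ev.precision["all"], recall=ev.recall["all"],
                   map50=ev.map50, lr=opt.lr)
        history.append(row)
        if ev.map50 > best_map:
            best_map, best_epoch = ev.map50, epoch
            best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(best_state)
    return TrainResult(best_state, best_map, best_epoch, history)


def save_run_artifacts(run_dir: str | Path, model: Detector,
                       result: TrainResult, config: TrainConfig):
    """Config snapshot, per-epoch CSV history, checkpoint, loss/PR curves."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    import json

    (run_dir / "config.json").write_text(json.dumps(
        {**dataclasses.asdict(config),
         "jitter_range": list(config.jitter_range)}, indent=2))
    with open(run_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(result.history[0].keys()))
        writer.writeheader()
        writer.writerows(result.history)
    save_checkpoint(run_dir / "best.npz", model)
    _plot_history(run_dir, result.history)


def _plot_history(run_dir: Path, history: list[dict]):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = [h["epoch"] for h in history]
    fig, axes = plt.subplots(2, 3, figsize=(12, 6))
    panels = [("loss_box", "box loss"), ("loss_obj", "objectness loss"),
              ("loss_cls", "class loss"), ("precision", "precision"),
              ("recall", "recall"), ("map50", "mAP@0.5")]
    for ax, (key, title) in zip(axes.ravel(), panels):
        ax.plot(epochs, [h[key] for h in history])
        ax.set_title(title)
        ax.set_xlabel("epoch")
    fig.tight_layout()
    fig.savefig(run_dir / "curves.png", dpi=100)
    plt.close(fig)
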