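"""Architecture-level accounting: parameters, layer counts, FLOPs.

FLOPs are measured by instrumenting the forward pass: every convolution
and fully connected primitive reports its multiply-accumulate count
exactly (``k^2 * Cin * Cout * Hout * Wout`` per conv), and one MAC is
counted as two FLOPs.  Batch-norm, activation and pooling traffic is
cheap elementwise work and is included only behind a flag.  The layer
count follows the module-summary convention documented on
:meth:`pestdet.network.Detector.layer_count`.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .network import Detector

_KNOWN_KINDS = {"conv2d", "linear", "batch_norm", "silu", "relu",
                "sigmoid", "max_pool2d"}


@dataclass(frozen=True)
class ComplexityReport:
    """One row of the complexity table."""

    name: str
    params: int
    layers: int
    gflops: float
    input_size: int

    @property
    def model_size_mb(self) -> float:
        """Assumed checkpoint size: parameters at half precision (2 bytes)."""
        return self.params * 2 / 1e6


def _trace_flops(model: Detector, input_size: int) -> list:
    if input_size % 32:
        raise ValueError(f"input size must be divisible by 32: {input_size}")
    was_training = model.training
    model.eval()
    try:
        with ag.no_grad(), ag.flop_recorder() as log:
            model.forward_tensors(Tensor(
                np.zeros((1, 3, input_size, input_size), dtype=np.float32)))
    finally:
        model.train(was_training)
    return log


def count_flops(model: Detector, input_size: int | None = None,
                include_elementwise: bool = False) -> float:
    """GFLOPs of one forward pass at ``input_size`` (MAC counted as 2 FLOPs).

    Unknown primitive kinds encountered in the trace are excluded with a
    warning.
    """
    input_size = input_size or model.spec.input_size
    total = 0.0
    for kind, macs, elemwise in _trace_flops(model, input_size):
        if kind not in _KNOWN_KINDS:
            warnings.warn(f"unsupported layer kind {kind!r} excluded from count")
            continue
        total += 2.0 * macs
        if include_elementwise:
            total += elemwise
    return total / 1e9


def count_macs_by_kind(model: Detector, input_size: int | None = None
                       ) -> dict[str, int]:
    """Raw multiply-accumulate totals per primitive kind (test hook)."""
    out: dict[str, int] = {}
    for kind, macs, _ in _trace_flops(model, input_size or model.spec.input_size):
        out[kind] = out.get(kind, 0) + macs
    return out


def layer_delta(model_a: Detector, model_b: Detector) -> int:
    """layer_count(b) - layer_count(a) under the shared convention."""
    return model_b.layer_count() - model_a.layer_count()


def report(models: list[Detector], input_size: int = 512
           ) -> list[ComplexityReport]:
    """One complexity row per model at the stated input size."""
    rows = []
    for m in models:
        rows.append(ComplexityReport(
            name=m.spec.name,
            params=m.num_params(),
            layers=m.layer_count(),
            gflops=count_flops(m, input_size),
            input_size=input_size,
        ))
    return rows


def report_csv(rows: list[ComplexityReport]) -> str:
    """CSV rendering: params, layers, GFLOPs, assumed model size.  An FPS
    column is deliberately absent — frame rate is hardware-dependent and
    outside this report's scope."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["model", "params", "layers",
                     f"gflops@{rows[0].input_size}" if rows else "gflops",
                     "model_size_mb_fp16"])
    for r in rows:
        writer.writerow([r.name, r.params, r.layers,
                         f"{r.gflops:.2f}", f"{r.model_size_mb:.2f}"])
    return buf.getvalue()
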