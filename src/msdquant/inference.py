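"""Bit-exact fixed-point CNN forward pass with MSD-approximated weights.

Placement of arithmetic mirrors the FPGA design: convolution and
fully-connected layers run on the shift-and-add MSD-MAC (weights stored as
packed MSD, at most ``p`` nonzero digits each, bias added as a binary
Q-format number, single saturation at read-out); batch normalization and
average pooling use general-purpose multiply/divide on Q-format numbers;
activations stay 16-bit signed Q-format throughout, with per-layer fraction
bits picked by a max-abs calibration pass.

All layer kernels work on int64 raw arrays.  Because the MAC unit keeps a
wide accumulator and saturates only once at read-out, an exact integer
matmul of the decoded weight raws is bit-identical to summing shift-and-add
partial products digit by digit — that identity is what lets the layers be
vectorized while staying faithful to the unit in :mod:`msdquant.mac`, and it
is checked against that unit in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .mac import rescale_raw_array
from .msd import naf_count_array, naf_value_array
from .nn import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Flatten,
    FloatModel,
    GlobalAvgPool,
    Linear,
    ReLU,
    ReLU6,
    ResidualBlock,
    _im2col,
)
from .packing import ApproxConfig, PackedMSDWeight, pack_weight
from .qformat import QFormatSpec, qformat_for, quantize_array
from .msd import BitVector, SignedDigitVector, binary_to_msd, truncate_msd

__all__ = [
    "ACTIVATION_WIDTH",
    "LayerStats",
    "RunStats",
    "EvalMetrics",
    "QuantizedModel",
    "quantize_model",
    "forward",
    "evaluate",
    "evaluate_float",
    "conv2d_msd",
    "depthwise_conv2d_msd",
    "linear_msd",
    "batchnorm_fixed",
    "avgpool_fixed",
    "relu_fixed",
    "residual_add",
]

ACTIVATION_WIDTH = 16  # signed Q-format bits carried between layers


@dataclass
class LayerStats:
    partial_sums: int = 0
    saturations: int = 0
    general_multiplies: int = 0


@dataclass
class RunStats:
    """Per-layer instrumentation collected during a forward pass."""

    layers: Dict[str, LayerStats] = field(default_factory=dict)

    def for_layer(self, name: str) -> LayerStats:
        return self.layers.setdefault(name, LayerStats())

    def total_partial_sums(self) -> int:
        return sum(s.partial_sums for s in self.layers.values())

    def total_saturations(self) -> int:
        return sum(s.saturations for s in self.layers.values())

    def as_dict(self) -> dict:
        return {
            name: {
                "partial_sums": s.partial_sums,
                "saturations": s.saturations,
                "general_multiplies": s.general_multiplies,
            }
            for name, s in self.layers.items()
        }


def _saturate_array(acc: np.ndarray, spec: QFormatSpec, stats: Optional[LayerStats]) -> np.ndarray:
    clipped = np.clip(acc, spec.min_raw, spec.max_raw)
    if stats is not None:
        stats.saturations += int(np.count_nonzero(clipped != acc))
    return clipped


def _bias_spec(max_abs: float, frac_bits: int) -> QFormatSpec:
    m = max(0, math.floor(math.log2(max_abs)) + 1) if max_abs > 0 else 0
    return QFormatSpec(m=m, n=frac_bits, signed=True)


# ---------------------------------------------------------------------------
# quantized layer specs


@dataclass
class QMacLayer:
    """Conv / depthwise-conv / linear layer on the MSD-MAC.

    ``weight_raw`` holds the decoded (already truncated) weight integers on
    the Q(m_w, n_w) raw scale; ``payloads`` is the packed W_M-bit container
    per weight, the storage format of record.  ``storage`` may be
    ``"qformat"`` for the plain fixed-point reference model, in which case
    weights are unapproximated Q-format raws and no packing exists.
    """

    kind: str  # conv2d | depthwise_conv2d | linear
    name: str
    weight_raw: np.ndarray
    weight_spec: QFormatSpec
    config: ApproxConfig
    bias_raw: Optional[np.ndarray]
    bias_spec: Optional[QFormatSpec]
    in_spec: QFormatSpec
    out_spec: QFormatSpec
    stride: int = 1
    pad: int = 0
    storage: str = "msd_packed"
    payloads: Optional[np.ndarray] = None  # uint16, same shape as weight_raw

    def digit_count(self) -> int:
        if self.storage == "msd_packed":
            return int(naf_count_array(self.weight_raw.ravel()).sum())
        return int(np.bitwise_count(np.abs(self.weight_raw.ravel()).astype(np.uint64)).sum())

    def apply(self, x: np.ndarray, stats: Optional[LayerStats] = None) -> np.ndarray:
        frac = self.weight_spec.n + self.in_spec.n
        if self.kind == "linear":
            acc = x.astype(np.int64) @ self.weight_raw.T.astype(np.int64)
            uses = x.shape[0]
        elif self.kind == "conv2d":
            c_out, c_in, kh, kw = self.weight_raw.shape
            cols, ho, wo = _im2col(x, kh, kw, self.stride, self.pad)
            wmat = self.weight_raw.reshape(c_out, -1).astype(np.int64)
            acc = np.einsum("of,nfl->nol", wmat, cols, dtype=np.int64)
            acc = acc.reshape(x.shape[0], c_out, ho, wo)
            uses = x.shape[0] * ho * wo
        elif self.kind == "depthwise_conv2d":
            c, kh, kw = self.weight_raw.shape
            cols, ho, wo = _im2col(x, kh, kw, self.stride, self.pad)
            cols = cols.reshape(x.shape[0], c, kh * kw, -1)
            wmat = self.weight_raw.reshape(c, -1).astype(np.int64)
            acc = np.einsum("cf,ncfl->ncl", wmat, cols, dtype=np.int64)
            acc = acc.reshape(x.shape[0], c, ho, wo)
            uses = x.shape[0] * ho * wo
        else:
            raise ValueError(f"unsupported MAC layer kind {self.kind!r}")
        if self.bias_raw is not None:
            b = self.bias_raw.astype(np.int64)
            if self.kind == "linear":
                acc = acc + b[None, :]
            else:
                acc = acc + b[None, :, None, None]
        out = rescale_raw_array(acc, frac - self.out_spec.n)
        if stats is not None:
            stats.partial_sums += self.digit_count() * uses
        return _saturate_array(out, self.out_spec, stats)


@dataclass
class QBatchNorm:
    """Folded batch normalization: y = scale * x + shift, general multiplier."""

    name: str
    scale_raw: np.ndarray
    scale_spec: QFormatSpec
    shift_raw: np.ndarray  # at fraction scale_spec.n + in_spec.n
    in_spec: QFormatSpec
    out_spec: QFormatSpec
    kind: str = "batchnorm"

    def apply(self, x: np.ndarray, stats: Optional[LayerStats] = None) -> np.ndarray:
        frac = self.scale_spec.n + self.in_spec.n
        acc = x.astype(np.int64) * self.scale_raw[None, :, None, None]
        acc = acc + self.shift_raw[None, :, None, None]
        out = rescale_raw_array(acc, frac - self.out_spec.n)
        if stats is not None:
            stats.general_multiplies += x.size
        return _saturate_array(out, self.out_spec, stats)


@dataclass
class QActivation:
    """relu / relu6 on the raw scale; format passes through unchanged."""

    name: str
    kind: str  # relu | relu6
    in_spec: QFormatSpec

    @property
    def out_spec(self) -> QFormatSpec:
        return self.in_spec

    def apply(self, x: np.ndarray, stats: Optional[LayerStats] = None) -> np.ndarray:
        x = np.maximum(x, 0)
        if self.kind == "relu6":
            six = min(6 << self.in_spec.n, self.in_spec.max_raw)
            x = np.minimum(x, six)
        return x


@dataclass
class QAvgPool:
    """Global average pooling: integer mean with round-half-up division."""

    name: str
    in_spec: QFormatSpec
    kind: str = "avgpool"

    @property
    def out_spec(self) -> QFormatSpec:
        return self.in_spec

    def apply(self, x: np.ndarray, stats: Optional[LayerStats] = None) -> np.ndarray:
        n, c, h, w = x.shape
        total = x.sum(axis=(2, 3), keepdims=True, dtype=np.int64)
        if stats is not None:
            stats.general_multiplies += n * c
        return (total + (h * w) // 2) // (h * w)


@dataclass
class QFlatten:
    name: str
    in_spec: QFormatSpec
    kind: str = "flatten"

    @property
    def out_spec(self) -> QFormatSpec:
        return self.in_spec

    def apply(self, x: np.ndarray, stats: Optional[LayerStats] = None) -> np.ndarray:
        return x.reshape(x.shape[0], -1)


@dataclass
class QResidual:
    """x + branch(x) with a saturating Q-format addition at the join."""

    name: str
    branch: list
    in_spec: QFormatSpec
    kind: str = "residual_add"

    @property
    def out_spec(self) -> QFormatSpec:
        return self.in_spec

    def apply(self, x: np.ndarray, stats_run: Optional["RunStats"] = None) -> np.ndarray:
        y = x
        for layer in self.branch:
            s = stats_run.for_layer(layer.name) if stats_run is not None else None
            y = _apply_layer(layer, y, s, stats_run)
        branch_spec = self.branch[-1].out_spec if self.branch else self.in_spec
        y = rescale_raw_array(y.astype(np.int64), branch_spec.n - self.in_spec.n)
        s = stats_run.for_layer(self.name) if stats_run is not None else None
        return _saturate_array(x.astype(np.int64) + y, self.in_spec, s)


QLayer = Union[QMacLayer, QBatchNorm, QActivation, QAvgPool, QFlatten, QResidual]


def _apply_layer(layer, x, stats, stats_run=None):
    if isinstance(layer, QResidual):
        return layer.apply(x, stats_run)
    return layer.apply(x, stats)


@dataclass
class QuantizedModel:
    """Ordered quantized layers plus the input activation format."""

    layers: List[QLayer]
    config: ApproxConfig
    input_spec: QFormatSpec

    def iter_mac_layers(self):
        def walk(layers):
            for l in layers:
                if isinstance(l, QResidual):
                    yield from walk(l.branch)
                elif isinstance(l, QMacLayer):
                    yield l
        return walk(self.layers)


@dataclass(frozen=True)
class EvalMetrics:
    """Classification metrics of one simulated run."""

    top1: float
    top2: float
    loss: float  # mean per-sample cross-entropy of soft-maxed logits
    precision: float  # macro-averaged over classes

    def __post_init__(self) -> None:
        if not (0.0 <= self.top1 <= self.top2 <= 1.0):
            raise ValueError("need 0 <= top1 <= top2 <= 1")


# ---------------------------------------------------------------------------
# model quantization


def _calibrate(float_model: FloatModel, calib: np.ndarray) -> Dict[int, float]:
    """Max-abs of every layer output (by id) over the calibration batch."""
    maxabs: Dict[int, float] = {}

    def run(layers, x):
        for layer in layers:
            if isinstance(layer, ResidualBlock):
                y = run(layer.branch, x)
                x = x + y
            else:
                x = layer.forward(x)
            maxabs[id(layer)] = max(maxabs.get(id(layer), 0.0), float(np.max(np.abs(x))))
        return x

    run(float_model.layers, calib)
    return maxabs


def _quantize_mac_layer(
    layer, name: str, cfg: ApproxConfig, in_spec: QFormatSpec,
    out_spec: QFormatSpec, msd: bool,
) -> QMacLayer:
    w = layer.params["w"]
    b = layer.params["b"]
    max_abs = float(np.max(np.abs(w)))
    wspec = qformat_for(max_abs if max_abs > 0 else 1.0, cfg.w_b, signed=True)
    layer_cfg = cfg.with_qspec(wspec)
    raw = quantize_array(w, wspec)
    payloads = None
    if msd:
        raw = naf_value_array(raw, cfg.p)
        payloads = np.empty(raw.shape, dtype=np.uint16)
        flat_r = raw.ravel()
        flat_p = payloads.ravel()
        for i, r in enumerate(flat_r):
            mag = int(abs(r))
            d = truncate_msd(binary_to_msd(BitVector.from_int(mag, layer_cfg.w_b)), cfg.p)
            if r < 0:
                d = d.negate()
            flat_p[i] = pack_weight(d, layer_cfg).payload
    frac = wspec.n + in_spec.n
    bspec = _bias_spec(float(np.max(np.abs(b))) if b.size else 0.0, frac)
    bias_raw = quantize_array(b, bspec)
    kind = layer.kind
    return QMacLayer(
        kind=kind,
        name=name,
        weight_raw=raw,
        weight_spec=wspec,
        config=layer_cfg,
        bias_raw=bias_raw,
        bias_spec=bspec,
        in_spec=in_spec,
        out_spec=out_spec,
        stride=getattr(layer, "stride", 1),
        pad=getattr(layer, "pad", 0),
        storage="msd_packed" if msd else "qformat",
        payloads=payloads,
    )


def quantize_model(
    float_model: FloatModel,
    cfg: ApproxConfig,
    calib: np.ndarray,
    msd: bool = True,
) -> QuantizedModel:
    """Quantize a float model for the fixed-point simulator.

    Conv and linear weights go through the full MSD approximation pipeline
    (per-tensor Q-format of width ``W_b``, NAF recoding, truncation to ``p``
    digits, packing); bias and normalization parameters are plain Q-format.
    ``calib`` is a float image batch (N, 1, H, W) used to pick per-layer
    activation fraction bits by max-abs scaling.  ``msd=False`` builds the
    plain fixed-point reference model (same formats, no MSD truncation).
    """
    maxabs = _calibrate(float_model, calib)
    in_max = float(np.max(np.abs(calib))) if calib.size else 1.0
    input_spec = qformat_for(max(in_max, 1e-9), ACTIVATION_WIDTH, signed=True)

    counter = [0]

    def act_spec(layer) -> QFormatSpec:
        return qformat_for(max(maxabs[id(layer)], 1e-9), ACTIVATION_WIDTH, signed=True)

    def convert(layers, in_spec: QFormatSpec) -> List[QLayer]:
        out: List[QLayer] = []
        spec = in_spec
        for layer in layers:
            counter[0] += 1
            name = f"{layer.kind}_{counter[0]}"
            if isinstance(layer, (Conv2d, DepthwiseConv2d, Linear)):
                ospec = act_spec(layer)
                out.append(_quantize_mac_layer(layer, name, cfg, spec, ospec, msd))
                spec = ospec
            elif isinstance(layer, BatchNorm2d):
                scale, shift = layer.scale_shift()
                sspec = qformat_for(float(np.max(np.abs(scale))) or 1.0,
                                    ACTIVATION_WIDTH, signed=True)
                ospec = act_spec(layer)
                frac = sspec.n + spec.n
                shift_spec = _bias_spec(float(np.max(np.abs(shift))) if shift.size else 0.0, frac)
                out.append(
                    QBatchNorm(
                        name=name,
                        scale_raw=quantize_array(scale, sspec),
                        scale_spec=sspec,
                        shift_raw=quantize_array(shift, shift_spec),
                        in_spec=spec,
                        out_spec=ospec,
                    )
                )
                spec = ospec
            elif isinstance(layer, (ReLU, ReLU6)):
                out.append(QActivation(name=name, kind=layer.kind, in_spec=spec))
            elif isinstance(layer, GlobalAvgPool):
                out.append(QAvgPool(name=name, in_spec=spec))
            elif isinstance(layer, Flatten):
                out.append(QFlatten(name=name, in_spec=spec))
            elif isinstance(layer, ResidualBlock):
                out.append(QResidual(name=name, branch=convert(layer.branch, spec), in_spec=spec))
            else:
                raise ValueError(f"unsupported layer kind {type(layer).__name__}")
        return out

    qlayers = convert(float_model.layers, input_spec)
    return QuantizedModel(layers=qlayers, config=cfg, input_spec=input_spec)


# ---------------------------------------------------------------------------
# forward pass and evaluation


def quantize_images(images: np.ndarray, spec: QFormatSpec) -> np.ndarray:
    """Map float images (N, H, W) or (N, 1, H, W) to input-format raws."""
    if images.ndim == 3:
        images = images[:, None, :, :]
    return quantize_array(images, spec)


def forward(
    model: QuantizedModel,
    batch: np.ndarray,
    stats: Optional[RunStats] = None,
) -> np.ndarray:
    """Run the fixed-point network on a quantized raw batch; returns raw logits.

    ``batch`` must already be on the input format's raw scale (int64, shape
    (N, 1, H, W)); use :func:`quantize_images`.  Deterministic: identical
    inputs and model give bit-identical logits.
    """
    x = np.asarray(batch, dtype=np.int64)
    for layer in model.layers:
        s = stats.for_layer(layer.name) if stats is not None else None
        x = _apply_layer(layer, x, s, stats)
    return x


def _metrics_from_logits(logits: np.ndarray, labels: np.ndarray, n_classes: int) -> EvalMetrics:
    order = np.argsort(-logits, axis=1, kind="stable")
    top1 = float(np.mean(order[:, 0] == labels))
    top2 = float(np.mean((order[:, :2] == labels[:, None]).any(axis=1)))
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    loss = float(-np.log(probs[np.arange(len(labels)), labels] + 1e-12).mean())
    pred = order[:, 0]
    precisions = []
    for k in range(n_classes):
        chosen = pred == k
        precisions.append(float(np.mean(labels[chosen] == k)) if chosen.any() else 0.0)
    return EvalMetrics(top1=top1, top2=top2, loss=loss, precision=float(np.mean(precisions)))


def evaluate(
    model: QuantizedModel,
    images: np.ndarray,
    labels: np.ndarray,
    n_classes: int = 7,
    stats: Optional[RunStats] = None,
) -> EvalMetrics:
    """Quantize images, run the fixed-point forward pass, score the logits."""
    if len(labels) == 0:
        raise ValueError("empty dataset")
    raw = quantize_images(images, model.input_spec)
    logits_raw = forward(model, raw, stats=stats)
    out_spec = model.layers[-1].out_spec
    logits = logits_raw.astype(np.float64) * out_spec.resolution
    return _metrics_from_logits(logits, labels, n_classes)


def evaluate_float(model: FloatModel, images: np.ndarray, labels: np.ndarray,
                   n_classes: int = 7) -> EvalMetrics:
    """Float-reference metrics of a fixture model on the same data."""
    if len(labels) == 0:
        raise ValueError("empty dataset")
    logits = model.forward(images[:, None, :, :])
    return _metrics_from_logits(logits, labels, n_classes)


# ---------------------------------------------------------------------------
# single-layer functional surface (thin wrappers over the layer objects)


def conv2d_msd(x: np.ndarray, layer: QMacLayer, stats: Optional[LayerStats] = None) -> np.ndarray:
    if layer.kind != "conv2d":
        raise ValueError("layer is not a conv2d")
    return layer.apply(x, stats)


def depthwise_conv2d_msd(x: np.ndarray, layer: QMacLayer, stats: Optional[LayerStats] = None) -> np.ndarray:
    if layer.kind != "depthwise_conv2d":
        raise ValueError("layer is not a depthwise conv2d")
    return layer.apply(x, stats)


def linear_msd(x: np.ndarray, layer: QMacLayer, stats: Optional[LayerStats] = None) -> np.ndarray:
    if layer.kind != "linear":
        raise ValueError("layer is not linear")
    return layer.apply(x, stats)


def batchnorm_fixed(x: np.ndarray, layer: QBatchNorm, stats: Optional[LayerStats] = None) -> np.ndarray:
    return layer.apply(x, stats)


def avgpool_fixed(x: np.ndarray, layer: QAvgPool, stats: Optional[LayerStats] = None) -> np.ndarray:
    return layer.apply(x, stats)


def relu_fixed(x: np.ndarray, layer: QActivation, stats: Optional[LayerStats] = None) -> np.ndarray:
    return layer.apply(x, stats)


def residual_add(x: np.ndarray, layer: QResidual, stats: Optional[RunStats] = None) -> np.ndarray:
    return layer.apply(x, stats)
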