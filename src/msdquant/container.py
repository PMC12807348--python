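"""On-disk model containers.

A container is a zip archive holding a human-readable JSON manifest
(``manifest.json``: layer list, Q-formats, approximation config, schema
version) plus one raw little-endian array file per parameter tensor.
Packed MSD weights are stored as ``<u2`` (one 16-bit payload per weight);
Q-format raws, biases and normalization parameters as ``<i8``; float fixture
models as ``<f8``.  Reading a quantized container reconstructs the decoded
weight integers by unpacking every payload, so the packed form is the
storage of record, and the save/load round trip is bit-exact.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path
from typing import List

import numpy as np

from . import nn
from .inference import (
    QActivation,
    QAvgPool,
    QBatchNorm,
    QFlatten,
    QMacLayer,
    QResidual,
    QuantizedModel,
)
from .packing import ApproxConfig, PackedMSDWeight
from .qformat import QFormatSpec

__all__ = ["save_quantized_model", "load_quantized_model", "save_float_model", "load_float_model", "ContainerError"]

FORMAT_NAME = "msdquant-container"
SCHEMA_VERSION = 1


class ContainerError(ValueError):
    """Raised when an archive is not a well-formed model container."""


def _spec_dict(spec: QFormatSpec) -> dict:
    return {"m": spec.m, "n": spec.n, "signed": spec.signed}


def _spec_from(d: dict) -> QFormatSpec:
    return QFormatSpec(m=d["m"], n=d["n"], signed=d["signed"])


class _Writer:
    def __init__(self, zf: zipfile.ZipFile):
        self.zf = zf
        self.count = 0

    def array(self, arr: np.ndarray, dtype: str) -> dict:
        name = f"arrays/{self.count:04d}.bin"
        self.count += 1
        self.zf.writestr(name, np.ascontiguousarray(arr, dtype=np.dtype(dtype)).tobytes())
        return {"file": name, "dtype": dtype, "shape": list(arr.shape)}


def _read_array(zf: zipfile.ZipFile, ref: dict) -> np.ndarray:
    raw = zf.read(ref["file"])
    return np.frombuffer(raw, dtype=np.dtype(ref["dtype"])).reshape(ref["shape"]).copy()


def _qlayer_manifest(layer, w: _Writer) -> dict:
    if isinstance(layer, QMacLayer):
        entry = {
            "kind": layer.kind,
            "name": layer.name,
            "storage": layer.storage,
            "weight_spec": _spec_dict(layer.weight_spec),
            "in_spec": _spec_dict(layer.in_spec),
            "out_spec": _spec_dict(layer.out_spec),
            "stride": layer.stride,
            "pad": layer.pad,
            "weight_shape": list(layer.weight_raw.shape),
        }
        if layer.storage == "msd_packed":
            entry["payloads"] = w.array(layer.payloads, "<u2")
        else:
            entry["weight_raw"] = w.array(layer.weight_raw, "<i8")
        if layer.bias_raw is not None:
            entry["bias_raw"] = w.array(layer.bias_raw, "<i8")
            entry["bias_spec"] = _spec_dict(layer.bias_spec)
        return entry
    if isinstance(layer, QBatchNorm):
        return {
            "kind": "batchnorm",
            "name": layer.name,
            "scale_raw": w.array(layer.scale_raw, "<i8"),
            "scale_spec": _spec_dict(layer.scale_spec),
            "shift_raw": w.array(layer.shift_raw, "<i8"),
            "in_spec": _spec_dict(layer.in_spec),
            "out_spec": _spec_dict(layer.out_spec),
        }
    if isinstance(layer, (QActivation, QAvgPool, QFlatten)):
        return {"kind": layer.kind, "name": layer.name, "in_spec": _spec_dict(layer.in_spec)}
    if isinstance(layer, QResidual):
        return {
            "kind": "residual_add",
            "name": layer.name,
            "in_spec": _spec_dict(layer.in_spec),
            "branch": [_qlayer_manifest(b, w) for b in layer.branch],
        }
    raise ContainerError(f"unsupported layer type {type(layer).__name__}")


def save_quantized_model(model: QuantizedModel, path) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        w = _Writer(zf)
        layers = [_qlayer_manifest(l, w) for l in model.layers]
        manifest = {
            "format": FORMAT_NAME,
            "version": SCHEMA_VERSION,
            "type": "quantized",
            "approx": {"p": model.config.p, "w_m": model.config.w_m},
            "input_spec": _spec_dict(model.input_spec),
            "layers": layers,
        }
        zf.writestr("manifest.json", json.dumps(manifest, indent=1, sort_keys=True))


def _load_qlayer(entry: dict, zf: zipfile.ZipFile, cfg: ApproxConfig):
    kind = entry["kind"]
    if kind in ("conv2d", "depthwise_conv2d", "linear"):
        wspec = _spec_from(entry["weight_spec"])
        layer_cfg = cfg.with_qspec(wspec)
        shape = tuple(entry["weight_shape"])
        if entry["storage"] == "msd_packed":
            payloads = _read_array(zf, entry["payloads"]).astype(np.uint16)
            flat = np.array(
                [PackedMSDWeight(int(p), layer_cfg).raw for p in payloads.ravel()],
                dtype=np.int64,
            )
            weight_raw = flat.reshape(shape)
        else:
            payloads = None
            weight_raw = _read_array(zf, entry["weight_raw"]).astype(np.int64).reshape(shape)
        bias_raw = bias_spec = None
        if "bias_raw" in entry:
            bias_raw = _read_array(zf, entry["bias_raw"]).astype(np.int64)
            bias_spec = _spec_from(entry["bias_spec"])
        return QMacLayer(
            kind=kind,
            name=entry["name"],
            weight_raw=weight_raw,
            weight_spec=wspec,
            config=layer_cfg,
            bias_raw=bias_raw,
            bias_spec=bias_spec,
            in_spec=_spec_from(entry["in_spec"]),
            out_spec=_spec_from(entry["out_spec"]),
            stride=entry["stride"],
            pad=entry["pad"],
            storage=entry["storage"],
            payloads=payloads,
        )
    if kind == "batchnorm":
        return QBatchNorm(
            name=entry["name"],
            scale_raw=_read_array(zf, entry["scale_raw"]).astype(np.int64),
            scale_spec=_spec_from(entry["scale_spec"]),
            shift_raw=_read_array(zf, entry["shift_raw"]).astype(np.int64),
            in_spec=_spec_from(entry["in_spec"]),
            out_spec=_spec_from(entry["out_spec"]),
        )
    if kind in ("relu", "relu6"):
        return QActivation(name=entry["name"], kind=kind, in_spec=_spec_from(entry["in_spec"]))
    if kind == "avgpool":
        return QAvgPool(name=entry["name"], in_spec=_spec_from(entry["in_spec"]))
    if kind == "flatten":
        return QFlatten(name=entry["name"], in_spec=_spec_from(entry["in_spec"]))
    if kind == "residual_add":
        return QResidual(
            name=entry["name"],
            branch=[_load_qlayer(b, zf, cfg) for b in entry["branch"]],
            in_spec=_spec_from(entry["in_spec"]),
        )
    raise ContainerError(f"unknown layer kind {kind!r}")


def _open_manifest(zf: zipfile.ZipFile, expected_type: str) -> dict:
    try:
        manifest = json.loads(zf.read("manifest.json"))
    except (KeyError, json.JSONDecodeError) as exc:
        raise ContainerError(f"malformed container: {exc}") from exc
    if manifest.get("format") != FORMAT_NAME or manifest.get("type") != expected_type:
        raise ContainerError("archive is not a container of the expected type")
    if manifest.get("version") != SCHEMA_VERSION:
        raise ContainerError(f"unsupported schema version {manifest.get('version')}")
    return manifest


def load_quantized_model(path) -> QuantizedModel:
    try:
        zf = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        raise ContainerError(f"cannot open container: {exc}") from exc
    with zf:
        manifest = _open_manifest(zf, "quantized")
        cfg = ApproxConfig(p=manifest["approx"]["p"], w_m=manifest["approx"]["w_m"])
        layers = [_load_qlayer(e, zf, cfg) for e in manifest["layers"]]
        return QuantizedModel(
            layers=layers,
            config=cfg,
            input_spec=_spec_from(manifest["input_spec"]),
        )


# ---------------------------------------------------------------------------
# float fixture models


def _float_layer_manifest(layer, w: _Writer) -> dict:
    entry: dict = {"kind": layer.kind}
    if isinstance(layer, nn.Conv2d):
        entry.update(c_in=layer.c_in, c_out=layer.c_out, k=layer.k,
                     stride=layer.stride, pad=layer.pad)
    elif isinstance(layer, nn.DepthwiseConv2d):
        entry.update(c=layer.c, k=layer.k, stride=layer.stride, pad=layer.pad)
    elif isinstance(layer, nn.Linear):
        entry.update(d_in=layer.params["w"].shape[1], d_out=layer.params["w"].shape[0])
    elif isinstance(layer, nn.BatchNorm2d):
        entry.update(c=layer.c, eps=layer.eps)
        entry["mean"] = w.array(layer.mean, "<f8")
        entry["var"] = w.array(layer.var, "<f8")
    elif isinstance(layer, nn.ResidualBlock):
        entry["branch"] = [_float_layer_manifest(b, w) for b in layer.branch]
        return entry
    for pname, arr in layer.params.items():
        entry.setdefault("params", {})[pname] = w.array(arr, "<f8")
    return entry


def save_float_model(model: nn.FloatModel, path) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        w = _Writer(zf)
        layers = [_float_layer_manifest(l, w) for l in model.layers]
        manifest = {
            "format": FORMAT_NAME,
            "version": SCHEMA_VERSION,
            "type": "float",
            "layers": layers,
        }
        zf.writestr("manifest.json", json.dumps(manifest, indent=1, sort_keys=True))


def _load_float_layer(entry: dict, zf: zipfile.ZipFile):
    kind = entry["kind"]
    if kind == "conv2d":
        layer = nn.Conv2d(entry["c_in"], entry["c_out"], k=entry["k"],
                          stride=entry["stride"], pad=entry["pad"])
    elif kind == "depthwise_conv2d":
        layer = nn.DepthwiseConv2d(entry["c"], k=entry["k"],
                                   stride=entry["stride"], pad=entry["pad"])
    elif kind == "linear":
        layer = nn.Linear(entry["d_in"], entry["d_out"])
    elif kind == "batchnorm":
        layer = nn.BatchNorm2d(entry["c"], eps=entry["eps"],
                               mean=_read_array(zf, entry["mean"]),
                               var=_read_array(zf, entry["var"]))
    elif kind == "relu":
        layer = nn.ReLU()
    elif kind == "relu6":
        layer = nn.ReLU6()
    elif kind == "avgpool":
        layer = nn.GlobalAvgPool()
    elif kind == "flatten":
        layer = nn.Flatten()
    elif kind == "residual_add":
        return nn.ResidualBlock([_load_float_layer(b, zf) for b in entry["branch"]])
    else:
        raise ContainerError(f"unknown float layer kind {kind!r}")
    for pname, ref in entry.get("params", {}).items():
        layer.params[pname] = _read_array(zf, ref)
    return layer


def load_float_model(path) -> nn.FloatModel:
    try:
        zf = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        raise ContainerError(f"cannot open container: {exc}") from exc
    with zf:
        manifest = _open_manifest(zf, "float")
        return nn.FloatModel([_load_float_layer(e, zf) for e in manifest["layers"]])
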