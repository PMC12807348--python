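"""Approximation-error metrics: NMED and nonzero-digit statistics.

NMED (normalized mean error distance) of an approximate multiplier is the
mean absolute output error over the operand domain divided by the maximum
exact output.  For the MSD-MAC the approximation error lives entirely in the
weight operand (the activation passes through exactly), so the mean over all
(weight, input) pairs factorizes::

    mean_{w,x} |w*x - w~*x| = mean_w |w - w~| * mean_x x        (x >= 0)

which turns the exhaustive 16-bit sweep (2^32 pairs) into two O(2^16)
passes.  The digit statistics count, per weight tensor, the shift-and-add
partial sums a MAC would execute under each representation: binary, full
MSD, and MSD truncated to a budget of p nonzero digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from .msd import naf_count_array, naf_value_array
from .packing import ApproxConfig
from .qformat import quantize_array

__all__ = ["ErrorReport", "DigitStats", "nmed", "nmed_pairwise", "digit_stats", "reduction_ratio"]


@dataclass(frozen=True)
class ErrorReport:
    """NMED of one approximate-multiplier configuration."""

    nmed: float  # dimensionless fraction
    mean_abs_error: float  # on the raw integer product scale
    max_output: int  # maximum exact product over the operand domain
    p: int
    operand_width: int

    @property
    def nmed_percent(self) -> float:
        return 100.0 * self.nmed

    def __post_init__(self) -> None:
        if self.nmed < 0:
            raise ValueError("NMED cannot be negative")


def _weight_domain(width: int, signed: bool) -> np.ndarray:
    if signed:
        return np.arange(-(1 << (width - 1)), 1 << (width - 1), dtype=np.int64)
    return np.arange(0, 1 << width, dtype=np.int64)


def approximate_raw_weights(w: np.ndarray, cfg: ApproxConfig, operand_width: int) -> np.ndarray:
    """Approximate integer weights of ``operand_width`` bits on their own scale.

    When the operand width exceeds the binary quantization width ``W_b`` the
    weight is first quantized to ``W_b``-bit resolution (drop the excess LSBs
    with round-half-away-from-zero), mirroring the float pipeline; the NAF
    truncation to ``p`` leading nonzero digits follows.
    """
    w = np.asarray(w, dtype=np.int64)
    shift = operand_width - cfg.w_b
    if shift > 0:
        scale = np.int64(1) << shift
        q = np.sign(w) * ((np.abs(w) + scale // 2) // scale)
        hi = (np.int64(1) << (cfg.w_b - 1 if cfg.qspec.signed else cfg.w_b)) - 1
        lo = -hi - 1 if cfg.qspec.signed else 0
        q = np.clip(q, lo, hi)
        return naf_value_array(q * scale, cfg.p)
    return naf_value_array(w, cfg.p)


def nmed(
    cfg: ApproxConfig,
    operand_width: int,
    signed_weights: Optional[bool] = None,
) -> ErrorReport:
    """Exhaustive NMED of the MSD-MAC multiplier at a given operand width.

    Weights sweep every representable ``operand_width``-bit integer (signed
    by default, per the Q-format convention of stored weights); activations
    sweep the unsigned ``operand_width``-bit range, matching post-ReLU
    activations.  Uses the factorized mean; no saturation is applied.
    """
    if operand_width < 1 or operand_width > 24:
        raise ValueError("operand width out of supported exhaustive range")
    if signed_weights is None:
        signed_weights = cfg.qspec.signed
    w = _weight_domain(operand_width, signed_weights)
    w_approx = approximate_raw_weights(w, cfg, operand_width)
    abs_err = np.abs(w - w_approx).astype(np.float64)
    x_max = (1 << operand_width) - 1
    mean_x = x_max / 2.0
    max_w = int(np.max(np.abs(w)))
    max_output = max_w * x_max
    mean_abs_error = float(abs_err.mean() * mean_x)
    return ErrorReport(
        nmed=mean_abs_error / max_output,
        mean_abs_error=mean_abs_error,
        max_output=max_output,
        p=cfg.p,
        operand_width=operand_width,
    )


def nmed_pairwise(
    cfg: ApproxConfig,
    operand_width: int,
    signed_weights: Optional[bool] = None,
) -> ErrorReport:
    """Reference NMED by direct enumeration of every (weight, input) pair.

    O(4^width); practical to ~10-bit operands.  Exists as the oracle the
    factorized path is checked against.
    """
    if operand_width > 12:
        raise ValueError("pairwise enumeration is limited to small widths")
    if signed_weights is None:
        signed_weights = cfg.qspec.signed
    w = _weight_domain(operand_width, signed_weights)
    w_approx = approximate_raw_weights(w, cfg, operand_width)
    x = np.arange(0, 1 << operand_width, dtype=np.int64)
    exact = np.outer(w, x)
    approx = np.outer(w_approx, x)
    err = np.abs(exact - approx)
    max_output = int(np.max(np.abs(exact)))
    mean_abs_error = float(err.mean())
    return ErrorReport(
        nmed=mean_abs_error / max_output,
        mean_abs_error=mean_abs_error,
        max_output=max_output,
        p=cfg.p,
        operand_width=operand_width,
    )


@dataclass(frozen=True)
class DigitStats:
    """Partial-sum counts of a weight tensor under each representation."""

    total_weights: int
    nonzero_digits_fp32: int  # ones in the stored float32 mantissa fields
    nonzero_digits_binary: int  # ones in the quantized binary magnitudes
    nonzero_digits_msd: int  # full NAF nonzero-digit count
    nonzero_digits_truncated: Dict[int, int]  # per digit budget p

    def __post_init__(self) -> None:
        if self.nonzero_digits_msd > self.nonzero_digits_binary:
            raise ValueError("MSD recoding cannot use more digits than binary")
        for p, c in self.nonzero_digits_truncated.items():
            if c > min(self.nonzero_digits_msd, p * self.total_weights):
                raise ValueError(f"truncated count at p={p} exceeds its bound")


def _fp32_mantissa_ones(weights: np.ndarray) -> int:
    """Ones in the 23-bit stored mantissa field of each float32 weight.

    Only mantissa-group bits feed multiplier partial products, so sign and
    exponent fields are not counted; the implicit leading 1 is not stored and
    is likewise excluded.
    """
    bits = np.asarray(weights, dtype=np.float32).view(np.uint32) & np.uint32(0x7FFFFF)
    return int(np.bitwise_count(bits).sum())


def digit_stats(
    weights: np.ndarray,
    cfg: ApproxConfig,
    ps: Sequence[int] = (1, 2, 3),
) -> DigitStats:
    """Count nonzero digits of a weight tensor under each representation.

    Weights are quantized to ``cfg.qspec``; the binary column counts ones in
    the quantized magnitude, the MSD column counts nonzero NAF digits, and
    each truncated column caps the NAF count at its budget ``p``.
    """
    w = np.asarray(weights, dtype=np.float64).ravel()
    raw = quantize_array(w, cfg.qspec)
    mags = np.abs(raw)
    binary = int(np.bitwise_count(mags.astype(np.uint64)).sum())
    naf_counts = naf_count_array(raw)
    msd = int(naf_counts.sum())
    truncated = {int(p): int(np.minimum(naf_counts, p).sum()) for p in ps}
    return DigitStats(
        total_weights=w.size,
        nonzero_digits_fp32=_fp32_mantissa_ones(w),
        nonzero_digits_binary=binary,
        nonzero_digits_msd=msd,
        nonzero_digits_truncated=truncated,
    )


def reduction_ratio(before: float, after: float) -> float:
    """Fractional reduction 1 - after/before between two partial-sum counts.

    Pass the two counts to compare, e.g. ``stats.nonzero_digits_fp32`` against
    ``stats.nonzero_digits_truncated[3]`` for the shift-and-add saving of the
    p = 3 scheme over float multiplication.
    """
    if before == 0:
        raise ZeroDivisionError("reference count is zero")
    return 1.0 - after / before
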