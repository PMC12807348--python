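"""Q(m, n) fixed-point formats and scalar fixed-point values.

A Q(m, n) number has ``m`` integer bits, ``n`` fraction bits and, if signed,
one sign bit, for a total width of ``m + n + signed``.  The real value of a
raw integer ``r`` stored in the format is ``r * 2**(-n)``.  All arithmetic in
this package is carried out on the raw integers; the format only fixes the
binary point and the representable range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["QFormatSpec", "FixedPointValue", "quantize_to_qformat", "qformat_for"]


@dataclass(frozen=True)
class QFormatSpec:
    """Fixed-point format Q(m, n): ``m`` integer bits, ``n`` fraction bits."""

    m: int
    n: int
    signed: bool = True

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError("integer and fraction bit counts must be >= 0")
        if self.width < 1:
            raise ValueError("zero-width format")

    @property
    def width(self) -> int:
        return self.m + self.n + (1 if self.signed else 0)

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.n)

    @property
    def min_raw(self) -> int:
        return -(1 << (self.m + self.n)) if self.signed else 0

    @property
    def max_raw(self) -> int:
        return (1 << (self.m + self.n)) - 1

    @property
    def min_value(self) -> float:
        return self.min_raw * self.resolution

    @property
    def max_value(self) -> float:
        return self.max_raw * self.resolution

    def clamp(self, raw: int) -> int:
        return min(max(int(raw), self.min_raw), self.max_raw)

    def clamp_array(self, raw: np.ndarray) -> np.ndarray:
        return np.clip(raw, self.min_raw, self.max_raw)

    def __str__(self) -> str:  # e.g. "Q(1,6)s8"
        return f"Q({self.m},{self.n}){'s' if self.signed else 'u'}{self.width}"


@dataclass(frozen=True)
class FixedPointValue:
    """A raw integer interpreted through a :class:`QFormatSpec`."""

    raw: int
    spec: QFormatSpec

    def __post_init__(self) -> None:
        if not (self.spec.min_raw <= self.raw <= self.spec.max_raw):
            raise ValueError(
                f"raw {self.raw} outside range of {self.spec}"
            )

    @property
    def value(self) -> float:
        return self.raw * self.spec.resolution

    def __float__(self) -> float:
        return self.value


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; numpy's round() ties to even, so do it by hand
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def quantize_to_qformat(w: float, spec: QFormatSpec) -> FixedPointValue:
    """Quantize a real number to ``spec``.

    Rounds half away from zero, then saturates to the representable range.
    """
    if not math.isfinite(w):
        raise ValueError(f"cannot quantize non-finite value {w!r}")
    return FixedPointValue(spec.clamp(_round_half_away(w * (1 << spec.n))), spec)


def quantize_array(w: np.ndarray, spec: QFormatSpec) -> np.ndarray:
    """Vectorized :func:`quantize_to_qformat`; returns int64 raw values."""
    w = np.asarray(w, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("cannot quantize non-finite values")
    scaled = w * (1 << spec.n)
    raw = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return spec.clamp_array(raw.astype(np.int64))


def qformat_for(max_abs: float, width: int, signed: bool = True) -> QFormatSpec:
    """Choose Q(m, n) with total ``width`` covering magnitudes up to ``max_abs``.

    ``m`` is the smallest integer-bit count whose range contains ``max_abs``
    (so an exact power of two stays representable), ``n = width - m - signed``;
    this is the per-tensor max-abs rule used for both weights and activations.
    """
    if max_abs <= 0:
        m = 0
    else:
        m = max(0, math.floor(math.log2(max_abs)) + 1)
    n = width - m - (1 if signed else 0)
    if n < 0:
        raise ValueError(f"width {width} too small for magnitude {max_abs}")
    return QFormatSpec(m=m, n=n, signed=signed)
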