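"""Bit-exact software model of the shift-and-add MAC unit.

The hardware multiplier takes a fixed weight in packed MSD form and a binary
Q-format activation.  Each nonzero weight digit contributes one partial sum:
the activation raw value shifted left by the digit position, added or
subtracted according to the digit sign.  Partial products accumulate in a
wide internal register; the accumulated raw value carries the combined
fraction bits of the two operand formats and is shifted back to the output
activation format (round-to-nearest-even) and saturated once, at read-out.

Keeping the accumulator wide and saturating only at read-out makes the MAC
result independent of summation order, which is what makes the vectorized
layer implementations in :mod:`msdquant.layers` bit-identical to this unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .packing import PackedMSDWeight
from .qformat import FixedPointValue, QFormatSpec

__all__ = ["MacCounters", "MacAccumulator", "msd_multiply", "mac", "saturate", "rescale_raw"]


@dataclass
class MacCounters:
    """Instrumentation: partial sums executed and saturation events."""

    partial_sums: int = 0
    saturations: int = 0

    def merge(self, other: "MacCounters") -> None:
        self.partial_sums += other.partial_sums
        self.saturations += other.saturations


def saturate(v: int, spec: QFormatSpec, counters: Optional[MacCounters] = None) -> FixedPointValue:
    """Clamp a wide integer to the representable raw range of ``spec``."""
    clamped = spec.clamp(v)
    if counters is not None and clamped != v:
        counters.saturations += 1
    return FixedPointValue(clamped, spec)


def rescale_raw(v: int, shift: int) -> int:
    """Shift a raw accumulator right by ``shift`` with round-to-nearest-even.

    ``shift <= 0`` is a plain left shift (gaining fraction bits is exact).
    """
    if shift <= 0:
        return v << (-shift)
    half = 1 << (shift - 1)
    floor = v >> shift
    rem = v & ((1 << shift) - 1)
    if rem > half or (rem == half and (floor & 1)):
        floor += 1
    return floor


def rescale_raw_array(v: np.ndarray, shift: int) -> np.ndarray:
    """Vectorized :func:`rescale_raw` on int64 arrays."""
    if shift <= 0:
        return v << (-shift)
    half = np.int64(1) << (shift - 1)
    floor = v >> shift  # arithmetic shift: floor division for negatives
    rem = v & ((np.int64(1) << shift) - 1)
    round_up = (rem > half) | ((rem == half) & ((floor & 1) == 1))
    return floor + round_up.astype(np.int64)


@dataclass
class MacAccumulator:
    """Wide accumulator of one MAC unit.

    ``frac_bits`` is the fraction-bit count carried by the accumulated raws
    (weight fraction + activation fraction); ``out_spec`` is the activation
    format produced at read-out.
    """

    out_spec: QFormatSpec
    frac_bits: int
    raw: int = 0
    counters: MacCounters = field(default_factory=MacCounters)

    def add_product(self, pw: PackedMSDWeight, x: FixedPointValue) -> None:
        d = pw.unpack()
        w = d.width
        for i, dig in enumerate(d.digits):
            if dig == 0:
                continue
            self.raw += dig * (x.raw << (w - 1 - i))
            self.counters.partial_sums += 1

    def add_bias(self, bias: FixedPointValue) -> None:
        # bias is stored as a binary Q-format number and added raw on the
        # accumulator scale
        if bias.spec.n > self.frac_bits:
            raise ValueError("bias has more fraction bits than the accumulator")
        self.raw += bias.raw << (self.frac_bits - bias.spec.n)

    def read_out(self) -> FixedPointValue:
        shifted = rescale_raw(self.raw, self.frac_bits - self.out_spec.n)
        return saturate(shifted, self.out_spec, self.counters)


def msd_multiply(
    pw: PackedMSDWeight,
    x: FixedPointValue,
    out_spec: Optional[QFormatSpec] = None,
    counters: Optional[MacCounters] = None,
) -> FixedPointValue:
    """Multiply a packed MSD weight by a Q-format activation.

    One shift-and-add partial sum per nonzero weight digit; the pre-saturation
    result equals the exact integer product of the decoded weight raw and the
    activation raw.  By default the product keeps all fraction bits of both
    operands (no precision loss before saturation).
    """
    frac = pw.config.qspec.n + x.spec.n
    if out_spec is None:
        # wide enough for any product of the two formats: no saturation
        out_spec = QFormatSpec(
            m=pw.config.qspec.m + x.spec.m + pw.config.w_b + 2, n=frac, signed=True
        )
    acc = MacAccumulator(out_spec=out_spec, frac_bits=frac)
    acc.add_product(pw, x)
    res = acc.read_out()
    if counters is not None:
        counters.merge(acc.counters)
    return res


def mac(
    pws: Sequence[PackedMSDWeight],
    xs: Sequence[FixedPointValue],
    bias: Optional[FixedPointValue] = None,
    out_spec: Optional[QFormatSpec] = None,
    counters: Optional[MacCounters] = None,
) -> FixedPointValue:
    """Dot product of packed weights and activations with one final saturation.

    Partial products accumulate at full precision; the bias (a plain binary
    Q-format number) is added to the accumulator; rescaling to ``out_spec``
    and saturation happen once at read-out.
    """
    if len(pws) != len(xs):
        raise ValueError(f"length mismatch: {len(pws)} weights, {len(xs)} inputs")
    frac = (pws[0].config.qspec.n if pws else (bias.spec.n if bias else 0)) + (
        xs[0].spec.n if xs else 0
    )
    if out_spec is None:
        if bias is not None and not pws:
            out_spec = bias.spec
        elif pws:
            out_spec = QFormatSpec(
                m=pws[0].config.qspec.m + xs[0].spec.m + pws[0].config.w_b + 12,
                n=frac,
                signed=True,
            )
        else:
            raise ValueError("empty MAC with no bias has no format")
    acc = MacAccumulator(out_spec=out_spec, frac_bits=frac)
    for pw, x in zip(pws, xs):
        if x.spec.n != xs[0].spec.n or pw.config.qspec.n != pws[0].config.qspec.n:
            raise ValueError("mixed operand Q-formats in one MAC")
        acc.add_product(pw, x)
    if bias is not None:
        acc.add_bias(bias)
    res = acc.read_out()
    if counters is not None:
        counters.merge(acc.counters)
    return res
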