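"""Packed storage of truncated MSD weights and the approximation pipeline.

A truncated MSD weight has at most ``p`` nonzero digits, so instead of two
bits per ternary digit it is stored in a fixed ``W_M``-bit container (16 by
default) holding ``p`` sign bits followed by ``p`` digit-position fields.
The full approximation pipeline for a floating-point weight is:

    quantize to a ``W_b``-bit Q(m, n) format  (W_b = W_M - p)
      -> recode the magnitude to non-adjacent form
      -> keep the p most-significant nonzero digits
      -> pack signs and positions into the W_M-bit payload

Packed layout (bit-exact, MSB first)::

    [ s_1 .. s_p | f_1 .. f_p | zero padding ]

    s_k : 1 sign bit per digit slot, 1 = negative digit
    f_k : position field of ceil(log2(W_b + 2)) bits holding (position + 1),
          slots ordered by descending position; 0 marks an empty slot

Storing ``position + 1`` (rather than the raw position) lets 0 mean "no
digit", so a weight with fewer than ``p`` nonzero digits — including zero
itself — packs unambiguously.  Positions run 0..W_b because NAF recoding can
carry one place past the quantized width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .msd import BitVector, SignedDigitVector, binary_to_msd, count_nonzero, truncate_msd
from .qformat import FixedPointValue, QFormatSpec, quantize_to_qformat

__all__ = [
    "ApproxConfig",
    "PackedMSDWeight",
    "pack_weight",
    "unpack_weight",
    "approximate_weight",
]

DEFAULT_WM = 16


@dataclass(frozen=True)
class ApproxConfig:
    """Knobs of the approximation scheme.

    p:     nonzero-digit budget kept after truncation (1, 2 or 3 in practice)
    w_m:   total bit-width of the packed MSD container (16 by default)
    qspec: Q-format of the intermediate binary quantization; its total width
           must equal ``w_b = w_m - p``
    """

    p: int
    w_m: int = DEFAULT_WM
    qspec: QFormatSpec = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"nonzero-digit budget must be >= 1, got {self.p}")
        if self.w_m <= self.p:
            raise ValueError("container width must exceed the digit budget")
        if self.qspec is None:
            # default: signed, all-fraction weights in (-1, 1)
            object.__setattr__(
                self, "qspec", QFormatSpec(m=0, n=self.w_b - 1, signed=True)
            )
        if self.qspec.width != self.w_b:
            raise ValueError(
                f"Q-format width {self.qspec.width} != W_b = W_M - p = {self.w_b}"
            )
        if self.payload_bits_used > self.w_m:
            raise ValueError(
                f"packed layout needs {self.payload_bits_used} bits, container "
                f"has {self.w_m}; the sign+position layout supports small digit "
                f"budgets only (p <= 3 at W_M = 16)"
            )

    @property
    def w_b(self) -> int:
        """Bit-width of the intermediate binary quantization."""
        return self.w_m - self.p

    @property
    def pos_field_bits(self) -> int:
        # fields store position+1 in 0..W_b+1, 0 = empty slot
        return math.ceil(math.log2(self.w_b + 2))

    @property
    def payload_bits_used(self) -> int:
        return self.p * (1 + self.pos_field_bits)

    def with_qspec(self, qspec: QFormatSpec) -> "ApproxConfig":
        return ApproxConfig(p=self.p, w_m=self.w_m, qspec=qspec)


@dataclass(frozen=True)
class PackedMSDWeight:
    """A truncated MSD weight in its ``W_M``-bit packed container."""

    payload: int
    config: ApproxConfig

    def __post_init__(self) -> None:
        if not (0 <= self.payload < (1 << self.config.w_m)):
            raise ValueError("payload does not fit the container width")

    def unpack(self) -> SignedDigitVector:
        return unpack_weight(self)

    @property
    def raw(self) -> int:
        """Decoded integer on the Q-format raw scale."""
        return self.unpack().value

    @property
    def value(self) -> float:
        """Decoded real weight value."""
        return self.raw * self.config.qspec.resolution

    def __str__(self) -> str:
        return str(self.unpack())


def pack_weight(d: SignedDigitVector, cfg: ApproxConfig) -> PackedMSDWeight:
    """Pack a truncated digit vector into the ``W_M``-bit payload."""
    nz = count_nonzero(d)
    if nz > cfg.p:
        raise ValueError(
            f"digit vector has {nz} nonzero digits, budget is {cfg.p}"
        )
    positions = d.nonzero_positions()
    if positions and positions[0] > cfg.w_b:
        raise ValueError(
            f"digit position {positions[0]} exceeds W_b = {cfg.w_b}"
        )
    digit_at = {pos: d.digits[d.width - 1 - pos] for pos in positions}
    fb = cfg.pos_field_bits
    sign_bits = 0
    pos_bits = 0
    for slot in range(cfg.p):
        sign_bits <<= 1
        pos_bits <<= fb
        if slot < len(positions):
            pos = positions[slot]
            sign_bits |= 1 if digit_at[pos] < 0 else 0
            pos_bits |= pos + 1
    payload = (sign_bits << (cfg.p * fb)) | pos_bits
    payload <<= cfg.w_m - cfg.payload_bits_used  # left-justify, zero padding
    return PackedMSDWeight(payload=payload, config=cfg)


def unpack_weight(pw: PackedMSDWeight) -> SignedDigitVector:
    """Inverse of :func:`pack_weight`; width is ``W_b + 1``."""
    cfg = pw.config
    fb = cfg.pos_field_bits
    body = pw.payload >> (cfg.w_m - cfg.payload_bits_used)
    pos_bits = body & ((1 << (cfg.p * fb)) - 1)
    sign_bits = body >> (cfg.p * fb)
    width = cfg.w_b + 1
    digits = [0] * width
    for slot in range(cfg.p):
        shift = fb * (cfg.p - 1 - slot)
        f = (pos_bits >> shift) & ((1 << fb) - 1)
        if f == 0:
            continue
        pos = f - 1
        neg = (sign_bits >> (cfg.p - 1 - slot)) & 1
        digits[width - 1 - pos] = -1 if neg else 1
    return SignedDigitVector(tuple(digits), width)


def approximate_weight(w: float, cfg: ApproxConfig) -> PackedMSDWeight:
    """Approximate one floating-point weight to at most ``p`` nonzero digits.

    The sign is handled by recoding the magnitude and negating every digit
    for a negative weight; signed digits make negation closed.
    """
    fx = quantize_to_qformat(w, cfg.qspec)
    mag = abs(fx.raw)
    d = binary_to_msd(BitVector.from_int(mag, cfg.w_b))
    d = truncate_msd(d, cfg.p)
    if fx.raw < 0:
        d = d.negate()
    return pack_weight(d, cfg)
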