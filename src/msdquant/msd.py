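"""Signed-digit (MSD / non-adjacent form) recoding of binary integers.

A minimum-signed-digit (MSD) representation writes an integer with digits in
{-1, 0, +1} using as few nonzero digits as possible.  The canonical such
representation is the non-adjacent form (NAF): no two adjacent digits are
nonzero, it is unique, and its nonzero-digit count is provably minimal over
all signed-digit representations of the value.  Every nonzero digit of a
weight costs one shift-and-add partial sum in a MAC unit, so minimising the
count — and then truncating it to a budget of ``p`` leading digits —
directly cuts multiplier work.

Digit vectors here are stored most-significant-digit first, like the printed
notation ``+00-`` for 8 - 1 = 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BitVector",
    "SignedDigitVector",
    "binary_to_msd",
    "msd_to_int",
    "truncate_msd",
    "count_nonzero",
    "naf_value_array",
    "naf_count_array",
]

_DIGIT_CHARS = {1: "+", 0: "0", -1: "-"}


@dataclass(frozen=True)
class BitVector:
    """An unsigned binary magnitude, most-significant bit first."""

    bits: tuple
    width: int

    def __post_init__(self) -> None:
        if self.width < 1 or len(self.bits) != self.width:
            raise ValueError("bit count must equal width")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")

    @classmethod
    def from_int(cls, x: int, width: int) -> "BitVector":
        if x < 0 or x >= (1 << width):
            raise ValueError(f"{x} does not fit in {width} unsigned bits")
        return cls(tuple((x >> k) & 1 for k in reversed(range(width))), width)

    def to_int(self) -> int:
        v = 0
        for b in self.bits:
            v = (v << 1) | b
        return v

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class SignedDigitVector:
    """Digits in {-1, 0, +1}, most-significant first."""

    digits: tuple
    width: int

    def __post_init__(self) -> None:
        if self.width < 1 or len(self.digits) != self.width:
            raise ValueError("digit count must equal width")
        if any(d not in (-1, 0, 1) for d in self.digits):
            raise ValueError("digits must be -1, 0 or +1")

    @property
    def value(self) -> int:
        return msd_to_int(self)

    def nonzero_positions(self) -> tuple:
        """Bit positions (LSB = 0) of the nonzero digits, descending."""
        w = self.width
        return tuple(w - 1 - i for i, d in enumerate(self.digits) if d != 0)

    def negate(self) -> "SignedDigitVector":
        return SignedDigitVector(tuple(-d for d in self.digits), self.width)

    def __str__(self) -> str:
        return "".join(_DIGIT_CHARS[d] for d in self.digits)

    @classmethod
    def from_string(cls, s: str) -> "SignedDigitVector":
        rev = {v: k for k, v in _DIGIT_CHARS.items()}
        return cls(tuple(rev[c] for c in s), len(s))


def binary_to_msd(x: BitVector) -> SignedDigitVector:
    """Recode an unsigned binary magnitude to its non-adjacent form.

    The output is one digit wider than the input because the recoding can
    carry one position past the MSB (e.g. 7 = 0111 -> +00-).  The result has
    the minimal nonzero-digit count over all signed-digit representations of
    the value, and no two adjacent digits are both nonzero.
    """
    v = x.to_int()
    digits = [0] * (x.width + 1)
    pos = 0
    # right-to-left NAF recoding: an odd residue takes digit 2 - (v mod 4),
    # which forces the next digit to zero
    while v > 0:
        if v & 1:
            d = 2 - (v & 3)
            digits[pos] = d
            v -= d
        v >>= 1
        pos += 1
    return SignedDigitVector(tuple(reversed(digits)), x.width + 1)


def msd_to_int(d: SignedDigitVector) -> int:
    """Decode a signed-digit vector: sum of digit * 2**position."""
    v = 0
    for dig in d.digits:
        v = (v << 1) + dig
    return v


def count_nonzero(d: SignedDigitVector) -> int:
    """Number of nonzero digits, i.e. shift-and-add partial sums required."""
    return sum(1 for dig in d.digits if dig != 0)


def truncate_msd(d: SignedDigitVector, p: int) -> SignedDigitVector:
    """Keep the ``p`` most-significant nonzero digits, zero the rest.

    Once the budget of ``p`` nonzero digits is spent, all less-significant
    digits are assumed zero.  If ``d`` already has at most ``p`` nonzero
    digits it is returned unchanged.
    """
    if p < 1:
        raise ValueError(f"nonzero-digit budget must be >= 1, got {p}")
    out = []
    kept = 0
    for dig in d.digits:
        if dig != 0 and kept < p:
            out.append(dig)
            kept += 1
        elif dig != 0:
            out.append(0)
        else:
            out.append(dig)
    return SignedDigitVector(tuple(out), d.width)


# ---------------------------------------------------------------------------
# vectorized paths (used by the exhaustive error analysis and property tests)


def naf_value_array(x: np.ndarray, p: int | None = None) -> np.ndarray:
    """NAF-recode an int64 array and decode after keeping ``p`` leading digits.

    ``p=None`` keeps every digit, making this recode-then-decode the identity.
    Negative entries are recoded by magnitude with all digits negated, which
    keeps truncation symmetric in sign.
    """
    x = np.asarray(x, dtype=np.int64)
    sign = np.sign(x)
    v = np.abs(x)
    width = int(v.max()).bit_length() if v.size else 0
    # digit d = 2 - (v mod 4) at each odd residue, LSB upward
    out = np.zeros_like(v)
    kept = np.zeros_like(v)
    digits = []  # (position, digit-array) pairs, LSB first
    for pos in range(width + 1):
        odd = (v & 1) == 1
        d = np.where(odd, 2 - (v & 3), 0)
        v = (v - d) >> 1
        digits.append(d)
    # keep the p most-significant nonzero digits: walk MSB downward
    for pos in range(len(digits) - 1, -1, -1):
        d = digits[pos]
        nz = d != 0
        if p is None:
            take = nz
        else:
            take = nz & (kept < p)
            kept = kept + nz.astype(np.int64)
        out = out + np.where(take, d << pos, 0)
    return out * sign


def naf_count_array(x: np.ndarray) -> np.ndarray:
    """Nonzero NAF digit count per element of an int64 array."""
    x = np.asarray(x, dtype=np.int64)
    v = np.abs(x)
    count = np.zeros_like(v)
    while np.any(v > 0):
        odd = (v & 1) == 1
        d = np.where(odd, 2 - (v & 3), 0)
        count += odd.astype(np.int64)
        v = (v - d) >> 1
    return count
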