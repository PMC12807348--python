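"""Shift-and-add MAC unit vs plain integer-multiplication oracle."""

import numpy as np
import pytest

from msdquant import (
    ApproxConfig,
    BitVector,
    FixedPointValue,
    MacCounters,
    QFormatSpec,
    binary_to_msd,
    count_nonzero,
    mac,
    msd_multiply,
    msd_to_int,
    pack_weight,
    saturate,
    truncate_msd,
)
from msdquant.mac import rescale_raw


def _packed(x: int, cfg: ApproxConfig):
    d = truncate_msd(binary_to_msd(BitVector.from_int(abs(x), cfg.w_b)), cfg.p)
    if x < 0:
        d = d.negate()
    return pack_weight(d, cfg), msd_to_int(d)


def _cfg_for_8bit(p: int) -> ApproxConfig:
    # 8-bit unsigned integer weights carried in the standard 16-bit container
    return ApproxConfig(p=p, w_m=16, qspec=QFormatSpec(16 - p, 0, signed=False))


class TestMsdMultiply:
    def test_seven_times_five_is_two_partial_sums(self):
        cfg = _cfg_for_8bit(3)
        pw, dec = _packed(7, cfg)
        counters = MacCounters()
        out = msd_multiply(pw, FixedPointValue(5, QFormatSpec(8, 0, signed=False)),
                           counters=counters)
        assert out.raw == 35
        assert counters.partial_sums == 2  # (5 << 3) - 5

    def test_six_times_three(self):
        cfg = _cfg_for_8bit(2)
        pw, _ = _packed(6, cfg)
        out = msd_multiply(pw, FixedPointValue(3, QFormatSpec(8, 0, signed=False)))
        assert out.raw == 18  # 24 - 6

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_exhaustive_8bit_oracle(self, p):
        cfg = _cfg_for_8bit(p)
        xspec = QFormatSpec(8, 0, signed=False)
        decoded = []
        packed = []
        for w in range(256):
            pw, dec = _packed(w, cfg)
            packed.append(pw)
            decoded.append(dec)
        # exhaustive sweep: shift-and-add over every (weight, input) pair,
        # vectorized over inputs, against the plain multiplication oracle
        xs = np.arange(256, dtype=np.int64)
        for w in range(256):
            d = packed[w].unpack()
            width = d.width
            shift_add = np.zeros_like(xs)
            for i, dig in enumerate(d.digits):
                if dig:
                    shift_add = shift_add + dig * (xs << (width - 1 - i))
            assert np.array_equal(shift_add, decoded[w] * xs)
        # and the scalar MAC unit itself on a dense grid of pairs
        for w in range(0, 256, 5):
            for x in range(0, 256, 17):
                assert msd_multiply(packed[w], FixedPointValue(x, xspec)).raw == decoded[w] * x

    def test_partial_sums_equal_nonzero_digit_count(self):
        xspec = QFormatSpec(8, 0, signed=False)
        for p in (1, 2, 3):
            cfg = _cfg_for_8bit(p)
            for w in (1, 7, 26, 170, 255):
                pw, _ = _packed(w, cfg)
                counters = MacCounters()
                msd_multiply(pw, FixedPointValue(9, xspec), counters=counters)
                assert counters.partial_sums == count_nonzero(pw.unpack())


class TestMac:
    def test_empty_sequences_return_bias(self):
        b = FixedPointValue(13, QFormatSpec(8, 0))
        assert mac([], [], bias=b).raw == 13

    def test_single_pair_plus_bias(self):
        cfg = _cfg_for_8bit(3)
        xspec = QFormatSpec(8, 0, signed=False)
        pw, dec = _packed(7, cfg)
        bias = FixedPointValue(10, QFormatSpec(16, 0))
        out = mac([pw], [FixedPointValue(5, xspec)], bias=bias)
        assert out.raw == dec * 5 + 10

    def test_dot_product_matches_integer_oracle(self):
        rng = np.random.default_rng(3)
        cfg = _cfg_for_8bit(3)
        xspec = QFormatSpec(8, 0, signed=False)
        for _ in range(20):
            ws = rng.integers(0, 256, size=8)
            xs = rng.integers(0, 256, size=8)
            pws, decs = zip(*(_packed(int(w), cfg) for w in ws))
            out = mac(list(pws), [FixedPointValue(int(x), xspec) for x in xs])
            assert out.raw == int(np.dot(decs, xs))

    def test_length_mismatch_rejected(self):
        cfg = _cfg_for_8bit(1)
        pw, _ = _packed(3, cfg)
        with pytest.raises(ValueError):
            mac([pw], [], bias=None)

    def test_accumulation_is_order_independent(self):
        rng = np.random.default_rng(11)
        cfg = _cfg_for_8bit(2)
        xspec = QFormatSpec(8, 0, signed=False)
        ws = rng.integers(0, 256, size=6)
        xs = rng.integers(0, 256, size=6)
        pws = [_packed(int(w), cfg)[0] for w in ws]
        fxs = [FixedPointValue(int(x), xspec) for x in xs]
        ref = mac(pws, fxs).raw
        for _ in range(5):
            perm = rng.permutation(6)
            assert mac([pws[i] for i in perm], [fxs[i] for i in perm]).raw == ref

    def test_saturation_applied_once_at_readout(self):
        # two large partial products whose sum is in range must not clip
        cfg = ApproxConfig(p=1, w_m=16, qspec=QFormatSpec(15, 0, signed=False))
        xspec = QFormatSpec(8, 0, signed=False)
        out_spec = QFormatSpec(16, 0, signed=True)
        pw_pos, _ = _packed(1 << 14, cfg)
        d = truncate_msd(binary_to_msd(BitVector.from_int(1 << 14, cfg.w_b)), 1).negate()
        pw_neg = pack_weight(d, cfg)
        counters = MacCounters()
        out = mac([pw_pos, pw_neg], [FixedPointValue(255, xspec)] * 2,
                  out_spec=out_spec, counters=counters)
        assert out.raw == 0
        assert counters.saturations == 0


class TestSaturate:
    def test_in_range_unchanged(self):
        q = QFormatSpec(3, 4)
        assert saturate(17, q).raw == 17

    def test_clamps_above_and_below(self):
        q = QFormatSpec(3, 4)
        assert saturate(q.max_raw + 1, q).raw == q.max_raw
        assert saturate(q.min_raw - 7, q).raw == q.min_raw

    def test_idempotent(self):
        q = QFormatSpec(2, 2)
        for v in (-1000, -3, 0, 5, 1000):
            once = saturate(v, q).raw
            assert saturate(once, q).raw == once


class TestRescale:
    def test_round_to_nearest_even(self):
        assert rescale_raw(6, 2) == 2  # 1.5 -> 2
        assert rescale_raw(10, 2) == 2  # 2.5 -> 2 (ties to even)
        assert rescale_raw(-6, 2) == -2
        assert rescale_raw(7, 2) == 2
        assert rescale_raw(9, 2) == 2

    def test_left_shift_for_negative_amounts(self):
        assert rescale_raw(3, -2) == 12
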