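"""Multiply with the shift-and-add MAC unit and count its partial sums.

A weight with d nonzero MSD digits costs exactly d shift-and-add partial
sums, which is the quantity the approximation scheme minimizes.
"""

from msdquant import (
    ApproxConfig,
    BitVector,
    FixedPointValue,
    MacCounters,
    QFormatSpec,
    binary_to_msd,
    mac,
    msd_multiply,
    pack_weight,
    truncate_msd,
)

cfg = ApproxConfig(p=3, w_m=16, qspec=QFormatSpec(13, 0, signed=False))
xspec = QFormatSpec(8, 0, signed=False)

for w, x in ((7, 5), (6, 3), (170, 9)):
    d = truncate_msd(binary_to_msd(BitVector.from_int(w, cfg.w_b)), cfg.p)
    pw = pack_weight(d, cfg)
    counters = MacCounters()
    out = msd_multiply(pw, FixedPointValue(x, xspec), counters=counters)
    dec = pw.raw
    print(f"{w:4d} * {x} -> {out.raw:5d}  digits {str(d).lstrip('0') or '0':>8}  "
          f"decoded {dec:4d}  partial sums {counters.partial_sums}")

# 7 = 8-1 costs two partial sums ((x<<3) - x); 170's four-digit form is
# truncated to three digits at p=3 (168), trading a small product error for
# one partial sum less.

weights, inputs = [7, 6, 3], [10, 20, 30]
pws = [pack_weight(truncate_msd(binary_to_msd(BitVector.from_int(w, cfg.w_b)), cfg.p), cfg)
       for w in weights]
fxs = [FixedPointValue(x, xspec) for x in inputs]
bias = FixedPointValue(100, QFormatSpec(16, 0))
counters = MacCounters()
res = mac(pws, fxs, bias=bias, counters=counters)
print(f"dot({weights}, {inputs}) + 100 = {res.raw}  "
      f"(partial sums {counters.partial_sums}, saturations {counters.saturations})")
# The accumulator is wide and saturates once at read-out, so the result is
# independent of accumulation order: 7*10 + 6*20 + 3*30 + 100 = 380.
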