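"""Exhaustive NMED of the truncated multiplier and digit statistics.

NMED (normalized mean error distance) = mean absolute product error over
the full operand domain, divided by the maximum exact product.  The digit
statistics count the shift-and-add partial sums a weight tensor costs under
each representation.
"""

import numpy as np

from msdquant import ApproxConfig, digit_stats, nmed, qformat_for, reduction_ratio

print("Exhaustive 16-bit NMED of the MSD-MAC multiplier")
print(f"{'p':>3} {'fraction':>10} {'percent':>9}")
for p in (3, 2, 1):
    rep = nmed(ApproxConfig(p=p), 16)
    print(f"{p:3d} {rep.nmed:10.6f} {rep.nmed_percent:9.4f}")
# Error grows steeply as the digit budget shrinks: each dropped digit
# roughly multiplies the mean truncation error by six.

print()
rng = np.random.default_rng(0)
w = rng.normal(0.0, 0.1, size=(3, 3, 64))  # a 576-weight first-layer tensor
cfg = ApproxConfig(p=3)
stats = digit_stats(w, cfg.with_qspec(qformat_for(float(np.max(np.abs(w))), cfg.w_b)))
print(f"Gaussian 3x3x64 tensor ({stats.total_weights} weights)")
print(f"  float32 mantissa ones : {stats.nonzero_digits_fp32}")
print(f"  binary (Q-format)     : {stats.nonzero_digits_binary}")
print(f"  full MSD              : {stats.nonzero_digits_msd}")
for p, c in sorted(stats.nonzero_digits_truncated.items()):
    r = reduction_ratio(stats.nonzero_digits_fp32, c)
    print(f"  truncated p={p}         : {c}   ({100 * r:.1f}% fewer than float)")
# The MSD recoding alone removes ~1/4 of the binary nonzero digits;
# truncation caps every weight at p partial sums.
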