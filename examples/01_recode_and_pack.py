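"""Recode weights to minimum-signed-digit form, truncate, and pack.

Shows the whole per-weight pipeline on a handful of values: Q-format
quantization, non-adjacent-form recoding, truncation to p nonzero digits,
and the 16-bit packed container.
"""

from msdquant import ApproxConfig, QFormatSpec, approximate_weight, count_nonzero

cfg = ApproxConfig(p=2, w_m=10, qspec=QFormatSpec(1, 6))
print(f"config: p={cfg.p}, W_M={cfg.w_m}, W_b={cfg.w_b}, qspec={cfg.qspec}")
print()
print(f"{'weight':>9} {'digits':>12} {'decoded':>9} {'nonzero':>8} {'payload':>8}")
for w in (0.40625, -0.40625, 0.5, 0.109375, 0.7):
    pw = approximate_weight(w, cfg)
    d = pw.unpack()
    print(f"{w:9.6f} {str(d):>12} {pw.value:9.6f} {count_nonzero(d):8d} "
          f"{pw.payload:#08x}")

# Each row: the float weight, its truncated signed-digit form (most
# significant digit first; + is +1, - is -1), the value it decodes back to,
# the number of shift-and-add partial sums a multiply now costs (at most p),
# and the 16-bit packed payload as stored.  0.40625 quantizes to 26/64 =
# +0-0+0 (32-8+2); keeping the 2 leading digits leaves 24/64 = 0.375.
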