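# Methods

This note records the model, the numerical conventions, and the design
choices made where the scheme leaves room, in the order the data flows.

## Signed-digit recoding

A signed-digit representation writes an integer x = Σ yₖ·2ᵏ with digits
yₖ ∈ {−1, 0, +1}. Among all such representations the *non-adjacent form*
(NAF) is canonical: it is unique, no two adjacent digits are nonzero, and
its nonzero-digit count is minimal — which is exactly the property a
shift-and-add multiplier cares about, since each nonzero digit is one
partial sum. The recoder works right-to-left: at every odd residue it emits
the digit d = 2 − (x mod 4) ∈ {+1, −1} and subtracts it, which forces the
next position to zero. The output is one digit wider than the input because
the recoding can carry past the MSB (7 = 0111 → +00−).

Lookup-table formulations of the same recoding exist that scan with an
explicit carry; the published table this package follows has internally
inconsistent rows as printed, so the implementation commits to the NAF
recurrence, whose minimality is checked in the tests against an independent
brute-force oracle (exhaustively to 12 bits) and whose non-adjacency is
checked exhaustively to 16 bits.

A consequence worth stating precisely: an *8-digit* MSD vector has at most
⌈8/2⌉ = 4 nonzero digits (non-adjacency), and every value whose NAF fits in
8 digits respects that bound. An 8-*bit binary* value can still need five
signed digits once the recoding carries into a ninth position
(171 = 256 − 64 − 16 − 4 − 1); the two statements are easy to conflate.

## Truncation and its error

Truncation keeps the p most significant nonzero digits and zeroes the rest
("digit budget" p; the practical settings are 3, 2, 1). Because the
discarded digits are non-adjacent and strictly below position k − 2p + 2
(k = leading-digit position), the absolute error is below 2^(k−p+1);
the bound is verified exhaustively at 12 bits. Truncation is performed on
the digit vector, so the leading digit may sit one position above the W_b
bit range (7 → 8); saturation happens only inside the MAC, never in the
representation.

Negative weights are recoded by magnitude with every digit negated — signed
digits make negation closed, so no separate sign bit is needed.

## Q-format conventions

Weights, biases, activations and normalization parameters are Q(m, n)
fixed-point numbers: m integer bits, n fraction bits, a sign bit when
signed, value = raw·2⁻ⁿ. Choices the scheme leaves open:

- **Per-tensor format.** m is the smallest integer-bit count whose range
  contains max|w| (so an exact power of two — weight 1.0, say — stays
  representable rather than saturating to 1 − 2⁻ⁿ), n = width − m − 1.
- **Rounding.** Quantization rounds half away from zero, then clamps.
- **Widths.** Weights use W_b = W_M − p bits (W_M = 16); activations are
  16-bit signed throughout, with per-layer n picked by a max-abs
  calibration pass over one batch (32 images by default).
- **Packed layout** (MSB first): p sign bits (1 = negative digit), then p
  position fields of ⌈log₂(W_b + 2)⌉ bits each holding *position + 1* in
  descending order, zero-padded to 16 bits. Storing position + 1 lets 0
  mean "empty slot", so weights with fewer than p nonzero digits — zero
  included — pack unambiguously (a field value of 0 can never collide with
  a genuine digit at position 0). The layout fits 16 bits for p ≤ 3;
  larger budgets are rejected at configuration time.

## The MAC unit

The multiplier takes the weight in packed MSD form and the activation as a
binary Q-format number; each nonzero digit contributes ±(x << k). Partial
products accumulate in a wide integer (Python integers in the scalar unit,
int64 in the vectorized layers), the bias is added on the accumulator scale
as a plain binary number, and the result is shifted back to the output
activation format with round-to-nearest-even and saturated **once, at
read-out**. Saturating only at read-out makes accumulation order-independent
and makes an exact integer dot product of the decoded weights bit-identical
to digit-by-digit accumulation — which is how the convolution and linear
layers can run as vectorized integer matmuls while remaining faithful to
the scalar unit (the parity is asserted in the tests). Whether real
hardware keeps full precision before saturating is an emulation convention
here, chosen for testability; per-partial-sum saturation would make results
depend on accumulation order.

Instrumentation counts partial sums (= nonzero digits × weight
applications) and saturation events per layer; both appear in simulator
reports.

## Error analysis

**NMED** of a multiplier configuration is the mean absolute product error
over the operand domain divided by the maximum exact output. Since the
approximation touches only the weight operand, the mean over all
(weight, input) pairs factorizes exactly as mean|w − w̃| · mean(x), making
the exhaustive 16-bit sweep O(2¹⁶); the factorized path is asserted equal
to the brute-force pairwise oracle at widths ≤ 10. Conventions: weights
sweep the full signed 16-bit domain (their stored format is signed),
activations the unsigned domain (post-ReLU); weights are first quantized to
W_b-bit resolution as in the float pipeline; no saturation enters the
metric; results are reported both as a fraction and in percent, because
published NMED tables for this scheme print unitless values whose scale is
not stated. The computed 16-bit values (0.13 / 0.77 / 4.63 percent for
p = 3 / 2 / 1) depend only on the uniform operand domain; NMED under a
trained network's actual weight distribution will differ, and the invariant
that transfers is the steep monotone growth of error as p shrinks.

**Digit statistics** count, per weight tensor, the partial sums implied by
each representation: ones in the stored float32 mantissa field (only
mantissa bits feed multiplier partial products; the implicit leading 1 is
not stored and not counted), ones in the quantized binary magnitude, full
NAF nonzero digits, and the NAF count capped at each budget p.

## Fixed-point inference

Layer placement mirrors the hardware design: conv, depthwise-conv and
linear layers run on the MSD MAC; batch normalization is folded at
quantization time into y = scale·x + shift (scale per-channel 16-bit
Q-format, shift on the product scale) and executed with general multipliers,
avoiding division at inference; average pooling divides with round-half-up;
ReLU/ReLU6 clamp raws; residual joins rescale the branch to the trunk
format and add with saturation. Images enter as x/255 quantized to the
input format. Everything is integer arithmetic, so runs are deterministic
to the bit.

Full-scale architectures are out of scope; the layer set supports their
building blocks (an inverted residual is conv + depthwise + conv +
residual join) and the fixtures instantiate miniatures.

## Synthetic fixtures

The dataset emulates a facial-expression benchmark in shape only: seven
classes of 48×48 grayscale images. Each class is a fixed template — an
oriented sinusoidal grating (orientation k·180°/7, wavelength 7 px) plus a
centred Gaussian blob whose width varies with the class — with per-sample
amplitude jitter (±15%) and additive Gaussian pixel noise (σ = 0.25 on the
[0, 1] scale), 60 samples per class split 2:1 train/test. Orientation makes
spatial filters informative and blob width makes channel mixing
informative, so depthwise and pointwise convolutions both matter. At zero
noise a linear template matcher is perfect; at the default noise the task
is easy for a small CNN but far from trivial for a collapsed one, which is
what the degradation experiment needs. What the fixtures deliberately do
not have: natural-image statistics, class imbalance, label noise, or the
inter-class similarity structure of real faces — so passing the trend tests
says the arithmetic and the pipeline behave correctly, not that any
particular accuracy would be achieved on a real benchmark.

The miniature models (conv 3×3/s2 → relu → depthwise 3×3/s2 → relu →
pointwise 1×1 → relu → global-avgpool → linear; a 2-layer "tiny" variant
for fast CLI tests) are trained by a small numpy Adam loop (im2col
convolutions, softmax cross-entropy, 25 epochs, batch 32, lr 5·10⁻³),
deterministic per seed. He-scaled initialization gives weights spanning
both signs and several octaves of magnitude, so truncation at p = 1 is
non-trivial on day one.

The degradation experiment (5 seeds, the sizes above, ~15 s total) measures
median test top-1 of the float reference and the p = 3, 2, 1 quantized
models. The expected and observed pattern: p = 3 within a few points of
float (occasionally above it — coarse weights act as a mild regularizer on
this easy task), monotone decline to p = 2, collapse at p = 1. Orderings
and margins are asserted, never absolute accuracies, which would be
properties of the synthetic task rather than of the arithmetic.

## Known limitations

- Timing, logic-element counts and memory placement are hardware properties
  and are not modelled; partial-sum counts are the software-visible proxy.
- The container stores one 16-bit payload per weight; sub-16-bit payload
  packing (p ≤ 2 uses fewer than 16 bits) is left as padding.
- The simulator targets small models; layers are vectorized but the
  framework is numpy, not a deployment runtime.
- NMED is computed for uniform operand distributions; distribution-weighted
  error metrics would need the target network's weights.
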