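# msdquant

Minimum-signed-digit (MSD) weight approximation for fixed-point CNN
inference, with a bit-exact software model of the shift-and-add MAC unit it
enables.

Embedded classifiers — the motivating case is on-device facial-emotion
recognition for patient monitoring, where images must not leave the device —
often run on FPGAs or microcontrollers without fast hardware multipliers.
There, the cost of a multiply is the number of partial sums it takes. A
weight written in a signed-digit (ternary, digits in {−1, 0, +1})
representation needs one shift-and-add per *nonzero* digit, so the fewer
nonzero digits, the cheaper the network. `msdquant` implements the full
post-training pipeline around this idea:

1. **Q-format quantization.** Each float weight w is quantized to a
   fixed-point format Q(m, n) of width W_b = W_M − p bits, where W_M = 16 is
   the stored container width and p the digit budget.
2. **MSD recoding.** The quantized magnitude is recoded to its non-adjacent
   form (NAF), the canonical minimum-signed-digit representation: no two
   adjacent digits are nonzero and the nonzero-digit count is provably
   minimal. Negative weights negate every digit.
3. **Truncation.** Only the p most significant nonzero digits are kept
   (p = 3, 2, 1 are the practical settings); every multiply then costs at
   most p partial sums.
4. **Packing.** The surviving digits are stored in a 16-bit container:
   p sign bits followed by p position fields.
5. **Shift-and-add MAC.** A software MAC unit multiplies packed weights by
   Q-format activations digit-by-digit, accumulates wide, adds the bias as a
   plain binary number and saturates once at read-out — bit-exactly the
   arithmetic a hardware unit would perform.

On top of the representation sit an exhaustive error analysis — NMED
(normalized mean error distance: mean |exact − approximate product| over the
whole operand domain divided by the maximum exact output) and per-tensor
digit statistics — and a fixed-point inference simulator that runs small
CNNs (conv, depthwise conv, pointwise conv, linear, folded batch-norm,
ReLU/ReLU6, average pooling, residual blocks) entirely in integer
arithmetic, with conv/linear layers on the MSD MAC and everything else on
general Q-format multipliers. Seeded synthetic fixtures (a 7-class 48×48
grayscale texture dataset and miniature CNNs with a minimal numpy training
loop) make every claim testable without external data.

## Worked example

```sh
python examples/04_fixed_point_inference.py
```

trains the miniature CNN on the synthetic 7-class set and simulates it at
each digit budget:

```
training loss 1.955 -> 0.439 over 25 epochs
     model    top1    top2    loss  partial sums
     float   0.986   1.000   0.413             -
       p=3   0.979   1.000   0.414      28733740
       p=2   0.957   1.000   0.482      19687360
       p=1   0.186   0.529   5.442       9853760
```

Three digits per weight track the float reference within a point of top-1
accuracy; one digit per weight needs a third of the shift-and-add work but
collapses toward chance (1/7) — the qualitative accuracy/efficiency
trade-off the scheme is designed to expose. The other examples walk the
per-weight pipeline (`01`), the MAC unit and its partial-sum counters
(`02`), and the exhaustive NMED / digit statistics (`03`).

The same flows are scriptable from a shell:

```sh
msdquant encode 7 --width 8 --p 1         # +000, value 8
msdquant nmed --p 3 --width 16            # exhaustive 16-bit NMED
msdquant fixture make-data -o data --seed 1
msdquant fixture make-model -o float.msdz --seed 1
msdquant quantize float.msdz -o q3.msdz --p 3 --calib data
msdquant simulate q3.msdz data --report report.json
```

`simulate` reports are deterministic: identical container, dataset and
configuration produce byte-identical files.

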