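"""Fixed-point layer semantics, quantization pipeline, and the simulator."""

import numpy as np
import pytest

from msdquant import (
    ApproxConfig,
    FixedPointValue,
    QFormatSpec,
    RunStats,
    evaluate,
    evaluate_float,
    forward,
    mac,
    quantize_images,
    quantize_model,
)
from msdquant.inference import (
    QActivation,
    QAvgPool,
    QBatchNorm,
    QMacLayer,
    QResidual,
    avgpool_fixed,
    batchnorm_fixed,
    conv2d_msd,
    relu_fixed,
)
from msdquant.msd import naf_value_array
from msdquant.nn import Conv2d, Flatten, FloatModel, GlobalAvgPool, Linear, ReLU
from msdquant.packing import pack_weight, ApproxConfig as _AC
from msdquant.msd import BitVector, binary_to_msd, truncate_msd
from msdquant.qformat import qformat_for, quantize_array


def _mac_layer(weight_raw, wspec, in_spec, out_spec, cfg, kind="conv2d", bias=None, **kw):
    return QMacLayer(
        kind=kind, name="t", weight_raw=np.asarray(weight_raw, dtype=np.int64),
        weight_spec=wspec, config=cfg.with_qspec(wspec), bias_raw=bias,
        bias_spec=None, in_spec=in_spec, out_spec=out_spec, storage="msd_packed", **kw,
    )


class TestMacLayers:
    def test_one_by_one_identity_conv(self):
        spec = QFormatSpec(1, 14)
        wspec = QFormatSpec(1, 11)  # weight 1.0 -> raw 2048
        cfg = ApproxConfig(p=3, w_m=16, qspec=wspec)
        layer = _mac_layer(np.full((1, 1, 1, 1), 1 << 11), wspec, spec, spec, cfg)
        x = np.arange(-8, 8, dtype=np.int64).reshape(1, 1, 4, 4)
        assert np.array_equal(layer.apply(x), x)

    def test_two_by_two_ones_kernel(self):
        spec = QFormatSpec(3, 12)
        wspec = QFormatSpec(1, 11)
        cfg = ApproxConfig(p=3, w_m=16, qspec=wspec)
        layer = _mac_layer(np.full((1, 1, 2, 2), 1 << 11), wspec, spec, spec, cfg)
        ones = np.full((1, 1, 2, 2), 1 << 12, dtype=np.int64)  # 1.0 in Q(3,12)
        out = layer.apply(ones)
        assert out.shape == (1, 1, 1, 1)
        assert out.ravel()[0] == 4 << 12  # exactly 4.0

    def test_conv_matches_integer_oracle(self):
        rng = np.random.default_rng(5)
        spec = QFormatSpec(7, 8)  # wide enough that nothing saturates
        wspec = QFormatSpec(0, 13)
        cfg = ApproxConfig(p=2, w_m=16, qspec=wspec)
        w_raw = naf_value_array(rng.integers(-4000, 4000, size=(3, 2, 3, 3)), 2)
        x = rng.integers(-100, 100, size=(2, 2, 4, 4)).astype(np.int64)
        layer = _mac_layer(w_raw, wspec, spec, spec, cfg, stride=1, pad=0)
        out = layer.apply(x)
        # brute-force integer convolution of the decoded weights
        from msdquant.mac import rescale_raw
        for n in range(2):
            for co in range(3):
                for i in range(2):
                    for j in range(2):
                        acc = int((w_raw[co] * x[n, :, i : i + 3, j : j + 3]).sum())
                        assert out[n, co, i, j] == rescale_raw(acc, wspec.n + spec.n - spec.n)

    def test_layer_parity_with_scalar_mac_unit(self):
        rng = np.random.default_rng(9)
        in_spec = QFormatSpec(3, 12)
        out_spec = QFormatSpec(4, 11)
        cfg = ApproxConfig(p=2, w_m=16)
        wspec = cfg.qspec
        w_raw = naf_value_array(rng.integers(-9000, 9000, size=(1, 1, 3, 3)), 2)
        bias = np.array([123], dtype=np.int64)
        layer = _mac_layer(w_raw, wspec, in_spec, out_spec, cfg, bias=bias)
        x = rng.integers(-2000, 2000, size=(1, 1, 3, 3)).astype(np.int64)
        out = layer.apply(x)
        # the same window through the scalar shift-and-add unit
        pws = []
        for r in w_raw.ravel():
            d = truncate_msd(binary_to_msd(BitVector.from_int(abs(int(r)), cfg.w_b)), 2)
            if r < 0:
                d = d.negate()
            pws.append(pack_weight(d, cfg))
        fxs = [FixedPointValue(int(v), in_spec) for v in x.ravel()]
        ref = mac(pws, fxs, bias=FixedPointValue(123, QFormatSpec(10, wspec.n + in_spec.n)),
                  out_spec=out_spec)
        assert out.ravel()[0] == ref.raw


class TestFixedLayers:
    def test_batchnorm_identity(self):
        spec = QFormatSpec(3, 12)
        sspec = QFormatSpec(1, 14)
        layer = QBatchNorm("bn", np.array([1 << 14]), sspec,
                           np.array([0]), spec, spec)
        x = np.arange(-6, 6, dtype=np.int64).reshape(1, 1, 3, 4)
        assert np.array_equal(batchnorm_fixed(x, layer), x)

    def test_batchnorm_scale_and_shift(self):
        spec = QFormatSpec(3, 8)
        sspec = QFormatSpec(1, 14)
        frac = sspec.n + spec.n
        shift_raw = np.array([3 << spec.n << sspec.n], dtype=np.int64)  # +3.0
        layer = QBatchNorm("bn", np.array([2 << 14]), sspec, shift_raw, spec, spec)
        x = np.full((1, 1, 1, 1), 1 << spec.n, dtype=np.int64)  # 1.0
        assert batchnorm_fixed(x, layer).ravel()[0] == 5 << spec.n  # 2*1+3

    def test_relu_zeroes_negatives(self):
        spec = QFormatSpec(3, 4)
        layer = QActivation("r", "relu", spec)
        x = -np.arange(1, 9, dtype=np.int64).reshape(1, 2, 2, 2)
        assert np.all(relu_fixed(x, layer) == 0)

    def test_relu6_clamps_at_six(self):
        spec = QFormatSpec(4, 8)
        layer = QActivation("r", "relu6", spec)
        x = np.array([[-5, 100 << 8, 3 << 8, 7 << 8]], dtype=np.int64).reshape(1, 4, 1, 1)
        out = relu_fixed(x, layer).ravel()
        assert list(out) == [0, 6 << 8, 3 << 8, 6 << 8]

    def test_avgpool_quarter_values_exact(self):
        spec = QFormatSpec(7, 8)
        layer = QAvgPool("p", spec)
        x = (np.array([1.0, 2.0, 3.0, 4.0]) * 256).astype(np.int64).reshape(1, 1, 2, 2)
        out = avgpool_fixed(x, layer)
        assert out.ravel()[0] == int(2.5 * 256)

    def test_residual_add_saturates(self):
        spec = QFormatSpec(2, 4)
        layer = QResidual("res", [], spec)
        x = np.full((1, 1, 1, 1), spec.max_raw, dtype=np.int64)
        out = layer.apply(x + 0)
        # branch is empty: y = x, so x + x must clip at the format maximum
        assert out.ravel()[0] == spec.max_raw


class TestQuantizeModel:
    def _small_model(self, seed=0):
        rng = np.random.default_rng(seed)
        return FloatModel([
            Conv2d(1, 4, k=3, stride=2, pad=1, rng=rng),
            ReLU(),
            GlobalAvgPool(),
            Flatten(),
            Linear(4, 3, rng=rng),
        ])

    def _calib(self, seed=0):
        rng = np.random.default_rng(seed + 100)
        return rng.uniform(0, 1, size=(8, 1, 12, 12))

    def test_all_zero_weights_emit_zero_logits(self):
        model = self._small_model()
        for layer in model.parameters():
            layer.params["w"][:] = 0.0
            layer.params["b"][:] = 0.0
        qm = quantize_model(model, ApproxConfig(p=2), self._calib())
        raw = quantize_images(self._calib()[:, 0], qm.input_spec)
        assert np.all(forward(qm, raw) == 0)

    def test_power_of_two_weight_exact_at_any_p(self):
        for p in (1, 2, 3):
            model = FloatModel([Conv2d(1, 1, k=1, rng=np.random.default_rng(0)),
                                Flatten(), Linear(144, 2, rng=np.random.default_rng(1))])
            model.layers[0].params["w"][:] = 1.0
            model.layers[0].params["b"][:] = 0.0
            qm = quantize_model(model, ApproxConfig(p=p), self._calib())
            conv = qm.layers[0]
            assert conv.weight_raw.ravel()[0] * conv.weight_spec.resolution == 1.0

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_per_weight_error_within_truncation_bound(self, p, trained_model, calib_batch):
        qm = quantize_model(trained_model, ApproxConfig(p=p), calib_batch)
        for layer, flayer in zip(qm.iter_mac_layers(),
                                 trained_model.parameters()):
            w = flayer.params["w"].ravel()
            dec = layer.weight_raw.ravel() * layer.weight_spec.resolution
            res = layer.weight_spec.resolution
            for wv, dv in zip(w, dec):
                q = quantize_array(np.array([wv]), layer.weight_spec)[0]
                if q == 0:
                    assert dv == 0.0
                    continue
                k = int(np.abs(naf_value_array(np.array([q]), 1))[0]).bit_length() - 1
                bound = (1 << max(0, k - p + 1)) * res
                assert abs(dv - wv) <= abs(q * res - wv) + bound

    def test_no_truncation_matches_plain_fixed_point(self, calib_batch):
        # float weights chosen to need at most 3 NAF digits, so p = 3
        # truncation is the identity and the MSD model must equal the plain
        # Q-format model bit-exactly
        model = self._small_model(seed=3)
        cfg = ApproxConfig(p=3)
        calib = self._calib(3)
        pre = quantize_model(model, cfg, calib, msd=False)
        for flayer, qlayer in zip(model.parameters(), pre.iter_mac_layers()):
            approx = naf_value_array(qlayer.weight_raw, 3)
            flayer.params["w"] = approx * qlayer.weight_spec.resolution
        q_msd = quantize_model(model, cfg, calib, msd=True)
        q_plain = quantize_model(model, cfg, calib, msd=False)
        raw = quantize_images(calib[:, 0], q_msd.input_spec)
        assert np.array_equal(forward(q_msd, raw), forward(q_plain, raw))


class TestEvaluate:
    def test_deterministic_bit_identical_logits(self, trained_model, dataset, calib_batch):
        qm = quantize_model(trained_model, ApproxConfig(p=2), calib_batch)
        raw = quantize_images(dataset.test_images[:16], qm.input_spec)
        assert np.array_equal(forward(qm, raw), forward(qm, raw.copy()))

    def test_constant_predictor_scores_prevalence(self):
        rng = np.random.default_rng(2)
        model = FloatModel([Flatten(), Linear(16, 3, rng=rng)])
        model.layers[1].params["w"][:] = 0.0
        model.layers[1].params["w"][1, :] = 1.0  # class 1 always wins
        model.layers[1].params["b"][:] = 0.0
        calib = rng.uniform(0, 1, size=(4, 1, 4, 4))
        qm = quantize_model(model, ApproxConfig(p=3), calib)
        images = rng.uniform(0, 1, size=(30, 4, 4))
        labels = np.array([0, 1, 2] * 10)
        m = evaluate(qm, images, labels, n_classes=3)
        assert m.top1 == pytest.approx(1 / 3)
        assert m.top1 <= m.top2 <= 1.0

    def test_empty_dataset_rejected(self, trained_model, calib_batch):
        qm = quantize_model(trained_model, ApproxConfig(p=3), calib_batch)
        with pytest.raises(ValueError):
            evaluate(qm, np.empty((0, 48, 48)), np.empty(0, dtype=int))

    def test_float_and_p3_metrics_close(self, trained_model, dataset, calib_batch):
        mf = evaluate_float(trained_model, dataset.test_images, dataset.test_labels)
        qm = quantize_model(trained_model, ApproxConfig(p=3), calib_batch)
        m3 = evaluate(qm, dataset.test_images, dataset.test_labels)
        assert abs(mf.top1 - m3.top1) < 0.1

    def test_partial_sum_instrumentation_counts(self, trained_model, dataset, calib_batch):
        qm = quantize_model(trained_model, ApproxConfig(p=1), calib_batch)
        stats = RunStats()
        evaluate(qm, dataset.test_images[:4], dataset.test_labels[:4], stats=stats)
        total = stats.total_partial_sums()
        assert total > 0
        # at p=1 every stored weight has at most one nonzero digit, so the
        # partial-sum count is bounded by one per weight application
        bound = 0
        for layer in qm.iter_mac_layers():
            uses = 4
            if layer.kind != "linear":
                # output spatial positions per image for 48x48 stride-2 stack
                uses = 4 * (48 // (2 ** 0)) ** 2  # loose upper bound
            bound += layer.weight_raw.size * uses
        assert total <= bound
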