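"""Network operations against brute-force oracles, causality and gradients."""

import math

import numpy as np
import pytest

from emgdecode import nn
from emgdecode.networks import (
    HybridModelConfig,
    LSTMConfig,
    TCNConfig,
    build_hybrid,
    causal_dilated_conv,
    count_parameters,
    hybrid_forward,
    lstm_cell,
    residual_block,
    tcn_forward,
)


def conv_oracle(x, filt, d):
    """Index-by-index loop: y[t] = sum_{k=1..K} f_k * x[t - (K-k)*d]."""
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    if filt.ndim == 1:
        filt = filt[:, None, None]
    k_size, _, c_out = filt.shape
    t_len = x.shape[0]
    y = np.zeros((t_len, c_out))
    for t in range(t_len):
        for k in range(1, k_size + 1):
            j = t - (k_size - k) * d
            if j >= 0:
                y[t] += filt[k - 1].T @ x[j]
    return y


class TestCausalDilatedConv:
    def test_hand_unrolled_example(self):
        out = causal_dilated_conv([1, 2, 3, 4], np.array([1.0, 1.0]), dilation=2)
        np.testing.assert_allclose(out, [1, 2, 4, 6])

    def test_k1_identity(self):
        x = np.arange(6.0)
        for d in (1, 3):
            np.testing.assert_allclose(
                causal_dilated_conv(x, np.array([1.0]), d), x
            )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            t, cin, cout = rng.integers(2, 12, size=3)
            k = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            x = rng.normal(size=(t, cin))
            filt = rng.normal(size=(k, cin, cout))
            np.testing.assert_allclose(
                causal_dilated_conv(x, filt, d), conv_oracle(x, filt, d), atol=1e-10
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            causal_dilated_conv(np.ones((5, 3)), np.ones((2, 4, 1)), 1)

    def test_causality(self, rng):
        x = rng.normal(size=(20, 2))
        filt = rng.normal(size=(3, 2, 4))
        base = causal_dilated_conv(x, filt, 2)
        x2 = x.copy()
        x2[10:] += rng.normal(size=(10, 2))
        pert = causal_dilated_conv(x2, filt, 2)
        np.testing.assert_array_equal(base[:10], pert[:10])


class TestResidualBlock:
    def test_zero_weights_identity_shortcut(self):
        cfg = TCNConfig(kernel_size=3, channels=4)
        block = nn.TemporalBlock(4, 4, 3, dilation=2)
        for p in block.params():
            p.value[...] = 0.0
        x = np.random.default_rng(0).normal(size=(7, 4))
        np.testing.assert_allclose(residual_block(x, cfg, 2, block=block), x)

    def test_projection_shortcut_shape(self, rng):
        cfg = TCNConfig(kernel_size=3, channels=6)
        out = residual_block(rng.normal(size=(9, 2)), cfg, 1, rng=rng)
        assert out.shape == (9, 6)

    def test_causality_probe(self, rng):
        cfg = TCNConfig(kernel_size=4, channels=3)
        block = nn.TemporalBlock(3, 3, 4, dilation=2, rng=rng)
        x = rng.normal(size=(15, 3))
        t0 = 8
        x2 = x.copy()
        x2[t0] += 1.0
        a = residual_block(x, cfg, 2, block=block)
        b = residual_block(x2, cfg, 2, block=block)
        np.testing.assert_array_equal(a[:t0], b[:t0])
        assert not np.allclose(a[t0:], b[t0:])


class TestTCNForward:
    def test_output_shape_even_for_short_input(self, rng):
        cfg = TCNConfig()  # receptive field 197
        out = tcn_forward(rng.normal(size=(10, 5)), cfg, rng=rng)
        assert out.shape == (10, 25)

    def test_zero_input_zero_params_gives_zero(self, rng):
        from emgdecode.networks import build_tcn

        cfg = TCNConfig(kernel_size=3, channels=4, dilations=(1, 2))
        model = build_tcn(3, cfg, rng=rng)
        for p in model.params():
            p.value[...] = 0.0
        out = tcn_forward(np.zeros((8, 3)), cfg, model=model)
        np.testing.assert_allclose(out, 0.0)

    def test_receptive_field_formula(self):
        assert TCNConfig().receptive_field == 197
        assert TCNConfig(kernel_size=2, dilations=(1, 2, 4)).receptive_field == 15

    def test_receptive_field_probe_k2(self, rng):
        """With K=2 and dilations (1,2,4), an input RF-1 steps back still
        influences the output while one step further back cannot."""
        from emgdecode.networks import build_tcn

        cfg = TCNConfig(kernel_size=2, channels=3, dilations=(1, 2, 4))
        rf = cfg.receptive_field
        model = build_tcn(1, cfg, rng=rng)
        # influence at the extreme lag flows through one tap chain; bias the
        # rectifiers into their active region so a dead unit cannot mask it
        for p in model.params():
            if p.name == "conv.bias":
                p.value[...] = 10.0
        t_len = rf + 5
        x = rng.normal(size=(t_len, 1))
        t_out = t_len - 1
        base = tcn_forward(x, cfg, model=model)

        inside = x.copy()
        inside[t_out - (rf - 1)] += 1.0
        assert not np.allclose(
            tcn_forward(inside, cfg, model=model)[t_out], base[t_out]
        )

        outside = x.copy()
        outside[t_out - rf] += 1.0
        np.testing.assert_array_equal(
            tcn_forward(outside, cfg, model=model)[t_out], base[t_out]
        )


def scalar_lstm_oracle(x, h, c, p):
    """Hand evaluation of the gate equations for 1 unit, 1 input."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    z = [h, x]
    dot = lambda w: w[0, 0] * z[0] + w[0, 1] * z[1]
    i = sig(dot(p["W_i"]) + p["b_i"][0])
    f = sig(dot(p["W_f"]) + p["b_f"][0])
    g = math.tanh(dot(p["W_g"]) + p["b_g"][0])
    o = sig(dot(p["W_o"]) + p["b_o"][0])
    c_new = f * c + i * g
    return o * math.tanh(c_new), c_new


class TestLSTMCell:
    def _zero_params(self, h, i):
        return {
            **{f"W_{g}": np.zeros((h, h + i)) for g in "ifgo"},
            **{f"b_{g}": np.zeros(h) for g in "ifgo"},
        }

    def test_all_zero(self):
        h, c = lstm_cell(np.zeros(3), np.zeros(2), np.zeros(2), self._zero_params(2, 3))
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(c, 0.0)

    def test_zero_weights_nonzero_cell(self):
        v = np.array([0.4, -1.2])
        h, c = lstm_cell(np.zeros(3), np.zeros(2), v, self._zero_params(2, 3))
        np.testing.assert_allclose(c, 0.5 * v)  # forget gate = sigmoid(0) = 0.5
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * v))

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            p = {
                **{f"W_{g}": rng.normal(size=(1, 2)) for g in "ifgo"},
                **{f"b_{g}": rng.normal(size=1) for g in "ifgo"},
            }
            x, h0, c0 = rng.normal(size=3)
            h, c = lstm_cell([x], [h0], [c0], p)
            h_ref, c_ref = scalar_lstm_oracle(x, h0, c0, p)
            assert h[0] == pytest.approx(h_ref, abs=1e-10)
            assert c[0] == pytest.approx(c_ref, abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            lstm_cell(np.zeros(3), np.zeros(2), np.zeros(2), self._zero_params(2, 4))

    def test_layer_agrees_with_cell(self, rng):
        """The batched BPTT layer and the per-step functional cell agree."""
        layer = nn.LSTMLayer(3, 4, rng=rng)
        w, b = layer.weight.value, layer.bias.value
        hs = 4
        p = {}
        for gi, g in enumerate("ifgo"):
            cols = slice(gi * hs, (gi + 1) * hs)
            p[f"W_{g}"] = w[:, cols].T
            p[f"b_{g}"] = b[cols]
        x = rng.normal(size=(6, 3))
        out = layer.forward(x[None])[0]
        h, c = np.zeros(4), np.zeros(4)
        for j in range(6):
            h, c = lstm_cell(x[j], h, c, p)
            np.testing.assert_allclose(out[j], h, atol=1e-10)


class TestHybridModel:
    def test_fused_width(self, rng):
        cfg = HybridModelConfig()
        model = build_hybrid(20, cfg, rng=rng)
        assert model.fused_dim == 45

    def test_output_shape(self, rng):
        cfg = HybridModelConfig(
            tcn=TCNConfig(kernel_size=3, channels=4, dilations=(1, 2)),
            lstm=LSTMConfig(layers=2, hidden_units=5),
        )
        out = hybrid_forward(rng.normal(size=(12, 6)), cfg, rng=rng)
        assert out.shape == (12,)

    def test_constant_input_settles(self, rng):
        cfg = HybridModelConfig(
            tcn=TCNConfig(kernel_size=2, channels=3, dilations=(1,)),
            lstm=LSTMConfig(layers=1, hidden_units=4),
        )
        model = build_hybrid(2, cfg, rng=rng)
        x = np.ones((300, 2)) * 0.3
        out = hybrid_forward(x, cfg, model=model)
        # LSTM state converges to a fixed point on constant input
        assert abs(out[-1] - out[-2]) < 1e-8

    def test_end_to_end_causality(self, rng):
        cfg = HybridModelConfig(
            tcn=TCNConfig(kernel_size=3, channels=4, dilations=(1, 2)),
            lstm=LSTMConfig(layers=2, hidden_units=5),
        )
        model = build_hybrid(3, cfg, rng=rng)
        x = rng.normal(size=(25, 3))
        base = hybrid_forward(x, cfg, model=model)
        x2 = x.copy()
        x2[15:] = rng.normal(size=(10, 3))
        pert = hybrid_forward(x2, cfg, model=model)
        np.testing.assert_array_equal(base[:15], pert[:15])

    def test_parameter_count_deterministic(self):
        cfg = HybridModelConfig()
        a = count_parameters(build_hybrid(20, cfg, rng=np.random.default_rng(0)))
        b = count_parameters(build_hybrid(20, cfg, rng=np.random.default_rng(99)))
        assert a == b > 0


class TestGradients:
    """Backward passes against central finite differences."""

    @staticmethod
    def _loss_and_grads(model, x, y):
        pred = model.forward(x, train=False)
        err = pred - y
        loss = float(np.mean(err**2))
        for p in model.params():
            p.zero_grad()
        model.backward(2.0 * err / err.size)
        return loss

    @pytest.mark.parametrize("which", ["conv", "lstm", "block", "hybrid"])
    def test_finite_difference(self, which, rng):
        if which == "conv":
            model = nn.Sequential([nn.CausalConv1d(2, 3, 3, 2, rng=rng), nn.Linear(3, 1, rng=rng)])
        elif which == "lstm":
            model = nn.Sequential([nn.LSTMLayer(2, 3, rng=rng), nn.Linear(3, 1, rng=rng)])
        elif which == "block":
            model = nn.Sequential([nn.TemporalBlock(2, 3, 2, 2, rng=rng), nn.Linear(3, 1, rng=rng)])
        else:
            cfg = HybridModelConfig(
                tcn=TCNConfig(kernel_size=2, channels=3, dilations=(1, 2)),
                lstm=LSTMConfig(layers=2, hidden_units=3),
            )
            model = build_hybrid(2, cfg, rng=rng)

        x = rng.normal(size=(2, 7, 2))
        y = rng.normal(size=(2, 7))

        class SqueezeHead:
            """Adapts a (B, T, 1)-output model to the (B, T) interface."""

            def __init__(self, m):
                self.m = m

            def forward(self, xx, train=False):
                return self.m.forward(xx, train=train)[..., 0]

            def backward(self, dy):
                return self.m.backward(dy[..., None])

            def params(self):
                return self.m.params()

        wrapped = model if hasattr(model, "fused_dim") else SqueezeHead(model)
        loss = self._loss_and_grads(wrapped, x, y)
        assert np.isfinite(loss)
        eps = 1e-6
        for p in model.params():
            flat = p.value.ravel()
            grad = p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(np.mean((wrapped.forward(x) - y) ** 2))
                flat[idx] = orig - eps
                down = float(np.mean((wrapped.forward(x) - y) ** 2))
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
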