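"""Layer operations against brute-force oracles and closed-form limits."""

import numpy as np
import pytest

from dacb import (
    DACBModel,
    ModelConfig,
    bilstm_forward,
    build_ablation_variant,
    conv1d_forward,
    dacb_forward,
    dot_attention,
    init_params,
    lstm_step,
    maxpool1d,
    se_excite,
    se_scale,
    se_squeeze,
)
from dacb.model import (
    AttentionParams,
    ConvParams,
    DenseParams,
    LSTMParams,
    SEParams,
    load_checkpoint,
    save_checkpoint,
)

RNG = np.random.default_rng(7)


def relu(v):
    return np.maximum(v, 0)


def conv_oracle(x, w, b):
    """Explicit sliding-window cross-correlation with zero same-padding."""
    L, cin = x.shape
    K, _, F = w.shape
    pad = K // 2
    xp = np.zeros((L + 2 * pad, cin))
    xp[pad : pad + L] = x
    out = np.zeros((L, F))
    for i in range(L):
        for f in range(F):
            acc = b[f]
            for k in range(K):
                for c in range(cin):
                    acc += xp[i + k, c] * w[k, c, f]
            out[i, f] = acc
    return relu(out)


class TestConv:
    def test_identity_kernel(self):
        w = np.zeros((3, 1, 1))
        w[1, 0, 0] = 1.0
        p = ConvParams(w=w, b=np.zeros(1))
        out = conv1d_forward(np.array([[1.0], [2.0], [3.0], [4.0]]), p)
        np.testing.assert_allclose(out[:, 0], [1, 2, 3, 4])

    def test_bias_only(self):
        p = ConvParams(w=np.zeros((3, 1, 2)), b=np.array([5.0, -1.0]))
        out = conv1d_forward(RNG.standard_normal((6, 1)), p)
        np.testing.assert_allclose(out[:, 0], 5.0)
        np.testing.assert_allclose(out[:, 1], 0.0)  # ReLU clips the -1 bias

    def test_matches_sliding_window_oracle(self):
        for _ in range(30):
            L, cin, F, K = RNG.integers(3, 9), RNG.integers(1, 3), RNG.integers(1, 4), 3
            x = RNG.standard_normal((L, cin))
            w = RNG.standard_normal((K, cin, F))
            b = RNG.standard_normal(F)
            out = conv1d_forward(x, ConvParams(w=w, b=b))
            np.testing.assert_allclose(out, conv_oracle(x, w, b), rtol=1e-10, atol=1e-12)

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            conv1d_forward(np.zeros((2, 1)), ConvParams(w=np.zeros((3, 1, 1)), b=np.zeros(1)))


class TestMaxPool:
    def test_window_maxima(self):
        np.testing.assert_allclose(maxpool1d(np.array([[1.0], [3.0], [2.0], [5.0]]), 2)[:, 0], [3, 5])

    def test_constant_input(self):
        out = maxpool1d(np.full((6, 3), 2.5), 3)
        np.testing.assert_allclose(out, 2.5)

    def test_matches_loop_oracle_with_remainder(self):
        x = RNG.standard_normal((11, 4))
        out = maxpool1d(x, 2)
        assert out.shape == (5, 4)
        for i in range(5):
            np.testing.assert_allclose(out[i], x[2 * i : 2 * i + 2].max(axis=0))

    def test_bad_pool(self):
        with pytest.raises(ValueError):
            maxpool1d(np.zeros((4, 1)), 0)


class TestSE:
    def test_squeeze_constant_and_mean(self):
        np.testing.assert_allclose(se_squeeze(np.full((3, 1), 2.0)), [2.0])
        np.testing.assert_allclose(se_squeeze(np.array([[1.0], [2.0], [3.0]])), [2.0])

    def test_squeeze_matches_loop(self):
        u = RNG.standard_normal((8, 4))
        expected = [sum(u[i, c] for i in range(8)) / 8 for c in range(4)]
        np.testing.assert_allclose(se_squeeze(u), expected, rtol=1e-12)

    def test_excite_zero_weights_give_half(self):
        p = SEParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)))
        np.testing.assert_allclose(se_excite(RNG.standard_normal(4), p), 0.5, atol=1e-15)

    def test_excite_open_unit_interval(self):
        p = SEParams(W1=RNG.standard_normal((2, 4)), W2=RNG.standard_normal((4, 2)))
        s = se_excite(RNG.standard_normal(4) * 3, p)
        assert np.all(s > 0) and np.all(s < 1)

    def test_excite_matches_two_layer_oracle(self):
        z = RNG.standard_normal(4)
        W1, W2 = RNG.standard_normal((2, 4)), RNG.standard_normal((4, 2))
        h = W1 @ z
        h = np.where(h > 0, h, np.exp(h) - 1)
        expected = 1 / (1 + np.exp(-(W2 @ h)))
        np.testing.assert_allclose(se_excite(z, SEParams(W1=W1, W2=W2)), expected, rtol=1e-12)

    def test_scale_identity_zero_and_product(self):
        u = RNG.standard_normal((5, 3))
        np.testing.assert_allclose(se_scale(u, np.ones(3)), u)
        np.testing.assert_allclose(se_scale(u, np.zeros(3)), 0.0)
        s = RNG.uniform(0, 1, 3)
        expected = [[u[i, c] * s[c] for c in range(3)] for i in range(5)]
        np.testing.assert_allclose(se_scale(u, s), expected, rtol=1e-12)

    def test_scale_length_mismatch(self):
        with pytest.raises(ValueError):
            se_scale(np.zeros((4, 3)), np.zeros(2))


def _lstm_params(H, F, fill=None, rng=None):
    shape = (H + F, H)
    if fill is not None:
        w = [np.full(shape, float(fill)) for _ in range(4)]
        b = [np.zeros(H) for _ in range(4)]
    else:
        w = [rng.standard_normal(shape) for _ in range(4)]
        b = [rng.standard_normal(H) for _ in range(4)]
    return LSTMParams(*w, *b)


class TestLSTMStep:
    def test_zero_weights_zero_state(self):
        p = _lstm_params(2, 1, fill=0.0)
        h, C = lstm_step([1.0], np.zeros(2), np.zeros(2), p)
        np.testing.assert_allclose(C, 0.0, atol=1e-15)
        np.testing.assert_allclose(h, 0.0, atol=1e-15)

    def test_zero_weights_closed_form(self):
        # f=i=o=0.5 so C_t = 0.5*C_prev and h_t = 0.5*tanh(0.5*C_prev)
        p = _lstm_params(3, 2, fill=0.0)
        C_prev = np.array([0.4, -1.2, 2.0])
        h, C = lstm_step(np.zeros(2), np.zeros(3), C_prev, p)
        np.testing.assert_allclose(C, 0.5 * C_prev, atol=1e-12)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * C_prev), atol=1e-12)

    def test_scalar_hand_computed_values(self):
        # weights 1, biases 0, x=1, h=C=0: all gate pre-activations are 1
        p = _lstm_params(1, 1, fill=1.0)
        h, C = lstm_step([1.0], [0.0], [0.0], p)
        sig1 = 1 / (1 + np.exp(-1.0))
        C_expected = sig1 * np.tanh(1.0)  # ~0.5568
        h_expected = sig1 * np.tanh(C_expected)  # ~0.3695
        np.testing.assert_allclose(C, [C_expected], rtol=1e-12)
        np.testing.assert_allclose(h, [h_expected], rtol=1e-12)
        assert C[0] == pytest.approx(0.5568, abs=2e-4)
        assert h[0] == pytest.approx(0.3696, abs=2e-4)

    def test_shape_mismatch(self):
        p = _lstm_params(2, 1, fill=0.0)
        with pytest.raises(ValueError):
            lstm_step([1.0, 2.0], np.zeros(2), np.zeros(2), p)


class TestBiLSTM:
    def test_palindrome_symmetry(self):
        # shared params on a palindromic sequence: the backward hidden
        # sequence is the reverse of the forward hidden sequence
        rng = np.random.default_rng(11)
        p = _lstm_params(3, 2, rng=rng)
        half = rng.standard_normal((4, 2))
        x = np.vstack([half, half[::-1]])
        out = bilstm_forward(x, p, p, merge="concat")
        fw, bw = out[:, :3], out[:, 3:]
        np.testing.assert_allclose(bw, fw[::-1], rtol=1e-10, atol=1e-12)

    def test_gated_merge_zero_weights(self):
        rng = np.random.default_rng(12)
        p = _lstm_params(2, 1, rng=rng)
        mp = DenseParams(W=np.zeros((4, 2)), b=np.zeros(2))
        out = bilstm_forward(rng.standard_normal((5, 1)), p, p, merge="gated", merge_p=mp)
        np.testing.assert_allclose(out, 0.5, atol=1e-15)

    def test_matches_unrolled_step_oracle(self):
        rng = np.random.default_rng(13)
        p_fw = _lstm_params(1, 1, rng=rng)
        p_bw = _lstm_params(1, 1, rng=rng)
        x = rng.standard_normal((2, 1))
        out = bilstm_forward(x, p_fw, p_bw, merge="concat")
        h, C = np.zeros(1), np.zeros(1)
        fw = []
        for t in range(2):
            h, C = lstm_step(x[t], h, C, p_fw)
            fw.append(h.copy())
        h, C = np.zeros(1), np.zeros(1)
        bw = {}
        for t in (1, 0):
            h, C = lstm_step(x[t], h, C, p_bw)
            bw[t] = h.copy()
        expected = np.array([[fw[0][0], bw[0][0]], [fw[1][0], bw[1][0]]])
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)


class TestDotAttention:
    def test_orthogonal_query_uniform_weights(self):
        V = RNG.standard_normal((3, 2))
        p = AttentionParams(W_a=np.zeros((2, 2)), q=np.array([1.0, 0.0]))
        a, d = dot_attention(V, p)
        np.testing.assert_allclose(d, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(a, V.mean(axis=0), rtol=1e-12)

    def test_weights_sum_to_one(self):
        for _ in range(20):
            n, dv = RNG.integers(1, 6), RNG.integers(1, 5)
            p = AttentionParams(W_a=RNG.standard_normal((dv, dv)), q=RNG.standard_normal(dv))
            a, d = dot_attention(RNG.standard_normal((n, dv)), p)
            assert abs(d.sum() - 1) < 1e-6 and np.all(d >= 0)

    def test_identity_case_formula_oracle(self):
        V = np.eye(2)
        p = AttentionParams(W_a=np.eye(2), q=np.array([1.0, 0.0]))
        a, d = dot_attention(V, p)
        scores = np.tanh(V) @ np.array([1.0, 0.0])  # [tanh(1), 0]
        e = np.exp(scores - scores.max())
        d_expected = e / e.sum()
        np.testing.assert_allclose(d, d_expected, rtol=1e-12)
        np.testing.assert_allclose(d, [0.682, 0.318], atol=5e-4)
        np.testing.assert_allclose(a, d_expected @ V, rtol=1e-12)


class TestDACBForward:
    def test_rows_sum_to_one(self, tiny_cfg):
        params = init_params(tiny_cfg)
        x = RNG.standard_normal((5, tiny_cfg.n_channels, 1))
        probs = dacb_forward(x, params, tiny_cfg)
        assert probs.shape == (5, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_batch_equivariance(self, tiny_cfg):
        params = init_params(tiny_cfg)
        x = RNG.standard_normal((6, tiny_cfg.n_channels, 1))
        perm = np.array([3, 1, 5, 0, 2, 4])
        probs = dacb_forward(x, params, tiny_cfg)
        probs_p = dacb_forward(x[perm], params, tiny_cfg)
        np.testing.assert_allclose(probs_p, probs[perm], rtol=1e-6, atol=1e-8)

    def test_composition_of_tested_operations(self, tiny_cfg):
        """The batched forward equals a layer-by-layer composition of the
        individually tested single-instance operations."""
        cfg = tiny_cfg
        params = init_params(cfg)
        x = RNG.standard_normal((3, cfg.n_channels, 1))
        probs = dacb_forward(x, params, cfg)

        def g(t):
            return t.data if hasattr(t, "data") else np.asarray(t)

        for i in range(3):
            xi = x[i]
            # spatial branch
            u = conv1d_forward(xi, params.conv)
            u = maxpool1d(u, cfg.pool_size)
            s = se_excite(se_squeeze(u), params.se)
            u = se_scale(u, s)
            vs = u.reshape(-1) @ g(params.proj_spatial.W) + g(params.proj_spatial.b)
            # temporal branch
            seq = bilstm_forward(xi, params.lstm_forward, params.lstm_backward, "concat")
            vt = seq.reshape(-1) @ g(params.proj_temporal.W) + g(params.proj_temporal.b)
            # fusion + head: attention weights scale the branch vectors,
            # which are then concatenated (weighted-concat default)
            V = np.stack([vs, vt])
            _, dwts = dot_attention(V, params.attention)
            fused = np.concatenate([dwts[0] * vs, dwts[1] * vt])
            h = relu(fused @ g(params.fc1.W) + g(params.fc1.b))
            h = relu(h @ g(params.fc2.W) + g(params.fc2.b))
            logits = h @ g(params.fc_out.W) + g(params.fc_out.b)
            e = np.exp(logits - logits.max())
            np.testing.assert_allclose(probs[i], e / e.sum(), rtol=1e-5, atol=1e-7)

    def test_shape_mismatch_rejected(self, tiny_cfg):
        params = init_params(tiny_cfg)
        with pytest.raises(ValueError):
            dacb_forward(RNG.standard_normal((2, tiny_cfg.n_channels + 1, 1)), params, tiny_cfg)


class TestAblationVariants:
    def test_block1_has_no_lstm_weights(self, tiny_cfg):
        m = build_ablation_variant(tiny_cfg, "block1_spatial_only")
        assert m.params.lstm_forward is None and m.params.lstm_backward is None
        assert m.params.conv is not None and m.params.se is not None

    def test_block2_has_no_conv_or_se_weights(self, tiny_cfg):
        m = build_ablation_variant(tiny_cfg, "block2_temporal_only")
        assert m.params.conv is None and m.params.se is None
        assert m.params.lstm_forward is not None

    def test_full_variant_equals_dacb_forward(self, tiny_cfg):
        m = build_ablation_variant(tiny_cfg, "full")
        x = RNG.standard_normal((4, tiny_cfg.n_channels, 1))
        np.testing.assert_allclose(
            m.predict_proba(x), dacb_forward(x, m.params, tiny_cfg), rtol=1e-6, atol=1e-8
        )

    def test_unknown_variant(self, tiny_cfg):
        with pytest.raises(ValueError):
            build_ablation_variant(tiny_cfg, "block3")

    def test_single_branch_rows_still_sum_to_one(self, tiny_cfg):
        x = RNG.standard_normal((3, tiny_cfg.n_channels, 1))
        for variant in ("block1_spatial_only", "block2_temporal_only"):
            probs = build_ablation_variant(tiny_cfg, variant).predict_proba(x)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestConfigAndCheckpoint:
    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ModelConfig(n_channels=8, n_classes=2, conv_filters=10, se_reduction=8)
        with pytest.raises(ValueError):
            ModelConfig(n_channels=8, n_classes=2, conv_kernel=4)
        with pytest.raises(ValueError):
            ModelConfig(n_channels=8, n_classes=2, attention_mode="global")

    def test_seeded_init_reproducible(self, tiny_cfg):
        a, b = init_params(tiny_cfg), init_params(tiny_cfg)
        for ta, tb in zip(a.tensors(), b.tensors()):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_checkpoint_round_trip(self, tiny_cfg, tmp_path):
        m = DACBModel(tiny_cfg)
        save_checkpoint(m, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        x = RNG.standard_normal((3, tiny_cfg.n_channels, 1))
        np.testing.assert_allclose(back.predict_proba(x), m.predict_proba(x), rtol=1e-7)

    def test_position_attention_mode_forward(self):
        cfg = ModelConfig(
            n_channels=8, n_classes=3, conv_filters=8, se_reduction=2,
            lstm_units=4, fusion_width=8, fc1_units=8, fc2_units=4,
            attention_mode="position", seed=3, dtype="float64",
        )
        probs = DACBModel(cfg).predict_proba(RNG.standard_normal((4, 8, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_gated_merge_forward(self):
        cfg = ModelConfig(
            n_channels=8, n_classes=3, conv_filters=8, se_reduction=2,
            lstm_units=4, fusion_width=8, fc1_units=8, fc2_units=4,
            bilstm_merge="gated", seed=3, dtype="float64",
        )
        probs = DACBModel(cfg).predict_proba(RNG.standard_normal((4, 8, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
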