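"""Forward-pass components against dense, term-by-term oracles."""

import numpy as np
import pytest

from stif import autodiff as ad
from stif.errors import DimensionError
from stif.model import (
    StnnConfig,
    build_mask,
    canonical_attention,
    continuous_attention,
    ffn_embed,
    init_params,
    load_checkpoint,
    residual_norm,
    save_checkpoint,
    stnn_forward,
    transformation_attention,
)


def dense_continuous_oracle(tokens, wq, wk, wv, scale_dim, mask=None):
    """Scalar-loop evaluation of exp(QK'/scale) V (the brute-force oracle)."""
    q, k, v = tokens @ wq, tokens @ wk, tokens @ wv
    n = tokens.shape[0]
    w = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            w[i, j] = np.exp(np.dot(q[i], k[j]) / scale_dim)
            if mask is not None and mask[i, j] == 0:
                w[i, j] = 0.0
    return w @ v


def dense_softmax_oracle(tokens, wq, wk, wv, scale_dim, mask=None):
    q, k, v = tokens @ wq, tokens @ wk, tokens @ wv
    n = tokens.shape[0]
    out = np.empty_like(tokens @ wv)
    for i in range(n):
        logits = np.array(
            [
                np.dot(q[i], k[j]) / np.sqrt(scale_dim)
                if (mask is None or mask[i, j]) else -np.inf
                for j in range(n)
            ]
        )
        e = np.exp(logits - logits[np.isfinite(logits)].max())
        out[i] = (e / e.sum()) @ v
    return out


class TestFfn:
    def test_identity_weight_passes_nonnegative_input(self):
        out = ffn_embed(np.array([0.5, 2.0]), np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, [0.5, 2.0])

    def test_elu_closed_form_below_zero(self):
        out = ffn_embed(np.array([7.0]), np.zeros((1, 1)), np.array([-1.0]))
        np.testing.assert_allclose(out, [np.exp(-1) - 1], atol=1e-12)

    def test_zero_input_zero_bias_gives_zero(self):
        out = ffn_embed(np.zeros(3), np.ones((3, 3)), np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            ffn_embed(np.zeros(3), np.eye(4), np.zeros(4))


class TestContinuousAttention:
    def test_zero_queries_sum_the_values(self, rng):
        tokens = rng.standard_normal((5, 1))
        wv = np.array([[1.0]])
        out, trace = continuous_attention(
            tokens, np.zeros((1, 8)), rng.standard_normal((1, 8)), wv, 8
        )
        np.testing.assert_allclose(out, np.full((5, 1), tokens.sum()), atol=1e-12)
        np.testing.assert_allclose(trace.weights, 1.0)

    @pytest.mark.parametrize("n_tokens", [2, 3, 4])
    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_dense_oracle(self, rng, n_tokens, masked):
        tokens = rng.standard_normal((n_tokens, 1))
        wq = rng.standard_normal((1, 2))
        wk = rng.standard_normal((1, 2))
        wv = rng.standard_normal((1, 1))
        mask = build_mask(n_tokens) if masked else None
        out, _ = continuous_attention(tokens, wq, wk, wv, 2, mask)
        oracle = dense_continuous_oracle(tokens, wq, wk, wv, 2, mask)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_masked_first_row_attends_only_to_itself(self, rng):
        tokens = rng.standard_normal((4, 1))
        wq, wk = rng.standard_normal((1, 3)), rng.standard_normal((1, 3))
        wv = rng.standard_normal((1, 1))
        out, _ = continuous_attention(tokens, wq, wk, wv, 3, build_mask(4))
        q, k, v = tokens @ wq, tokens @ wk, tokens @ wv
        expected = np.exp(np.dot(q[0], k[0]) / 3) * v[0]
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_logit_clip_keeps_weights_finite(self):
        tokens = np.full((2, 1), 100.0)
        wq = wk = np.array([[10.0]])
        wv = np.array([[1.0]])
        out, trace = continuous_attention(tokens, wq, wk, wv, 1)
        assert np.all(np.isfinite(out))
        assert trace.weights.max() <= np.exp(50.0)


class TestCanonicalAttention:
    def test_equal_logits_give_uniform_weights(self):
        tokens = np.ones((4, 1))
        wq = wk = np.ones((1, 2))
        wv = np.array([[1.0]])
        _, trace = canonical_attention(tokens, wq, wk, wv, 2)
        np.testing.assert_allclose(trace.weights, 0.25, atol=1e-12)

    def test_self_only_mask_gives_weight_one(self, rng):
        tokens = rng.standard_normal((3, 1))
        mask = np.eye(3)
        _, trace = canonical_attention(
            tokens, rng.standard_normal((1, 2)), rng.standard_normal((1, 2)),
            np.array([[1.0]]), 2, mask,
        )
        np.testing.assert_allclose(trace.weights, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("n_tokens", [2, 3, 4])
    def test_matches_dense_softmax_oracle(self, rng, n_tokens):
        tokens = rng.standard_normal((n_tokens, 1))
        wq = rng.standard_normal((1, 2))
        wk = rng.standard_normal((1, 2))
        wv = rng.standard_normal((1, 1))
        out, trace = canonical_attention(tokens, wq, wk, wv, 2)
        oracle = dense_softmax_oracle(tokens, wq, wk, wv, 2)
        np.testing.assert_allclose(out, oracle, atol=1e-10)
        np.testing.assert_allclose(trace.weights.sum(axis=-1), 1.0, atol=1e-12)


class TestResidualNorm:
    def test_constant_input_is_centered_to_zero(self):
        out = residual_norm(np.full((4, 1), 3.0), np.full((4, 1), 2.0))
        np.testing.assert_allclose(ad.value_of(out), 0.0, atol=1e-2)

    def test_output_standardized_over_tokens(self, rng):
        base = rng.standard_normal((6, 1))
        out = ad.value_of(residual_norm(base, np.zeros((6, 1))))
        assert abs(out.mean()) < 1e-10
        assert abs(out.std() - 1.0) < 1e-2  # epsilon slightly shrinks the SD

    def test_hand_case_one_two_three(self):
        out = ad.value_of(residual_norm(np.array([[1.0], [2.0], [3.0]]), np.zeros((3, 1))))
        np.testing.assert_allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-3)


class TestTransformationAttention:
    def test_all_ones_spatial_column_scales_to_identity(self, rng):
        d = 7
        tsa = rng.standard_normal((3, 1))
        ssa = np.ones((d, 1))
        out = transformation_attention(tsa, ssa, d)
        np.testing.assert_allclose(out, tsa, atol=1e-12)

    def test_zero_temporal_gives_zero(self, rng):
        out = transformation_attention(np.zeros((3, 1)), rng.standard_normal((5, 1)), 5)
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_triple_product_oracle(self, rng):
        tsa = rng.standard_normal((3, 1))
        ssa = rng.standard_normal((4, 1))
        out = transformation_attention(tsa, ssa, 4)
        oracle = (tsa @ ssa.T @ ssa) / 4
        np.testing.assert_allclose(out, oracle, atol=1e-12)


class TestMask:
    def test_patterns(self):
        np.testing.assert_array_equal(build_mask(1), [[1.0]])
        np.testing.assert_array_equal(
            build_mask(3), [[1, 0, 0], [1, 1, 0], [1, 1, 1]]
        )

    def test_row_sums_count_visible_history(self):
        m = build_mask(6)
        np.testing.assert_array_equal(m.sum(axis=1), np.arange(1, 7))


class TestForward:
    @pytest.fixture
    def small(self):
        config = StnnConfig(D=4, L=3, d_E=5, d_D=5, seed=0)
        return config, init_params(config)

    def test_masked_attention_is_causal_by_finite_differences(self, rng):
        """Row i of masked temporal attention has zero gradient w.r.t.
        tokens j > i: the mask blocks all forward information flow."""
        n, w = 5, 2
        tokens = rng.standard_normal((n, w))
        wq = rng.standard_normal((w, 3))
        wk = rng.standard_normal((w, 3))
        wv = rng.standard_normal((w, w))
        mask = build_mask(n)
        base, _ = continuous_attention(tokens, wq, wk, wv, 3, mask)
        eps = 1e-6
        for j in range(n):
            for f in range(w):
                up, dn = tokens.copy(), tokens.copy()
                up[j, f] += eps
                dn[j, f] -= eps
                fu, _ = continuous_attention(up, wq, wk, wv, 3, mask)
                fd, _ = continuous_attention(dn, wq, wk, wv, 3, mask)
                grad = (fu - fd) / (2 * eps)
                # rows strictly before token j must have exactly zero gradient
                np.testing.assert_array_equal(grad[:j], 0.0)

    def test_literal_mask_reading_leaks_future_information(self, rng):
        """Multiplying logits by the mask inside exp (the literal equation)
        gives excluded positions weight exp(0)=1 — future tokens leak."""
        n = 4
        tokens = rng.standard_normal((n, 1))
        wq, wk = rng.standard_normal((1, 2)), rng.standard_normal((1, 2))
        wv = rng.standard_normal((1, 1))
        mask = build_mask(n)
        base, _ = continuous_attention(
            tokens, wq, wk, wv, 2, mask, literal_mask=True
        )
        bumped = tokens.copy()
        bumped[-1] += 0.5
        out, _ = continuous_attention(
            bumped, wq, wk, wv, 2, mask, literal_mask=True
        )
        assert not np.allclose(out[0], base[0])

    def test_zero_prefix_hides_the_one_step_ahead_truth(self, small):
        """The final window position never observes its own target: the
        decoder input is the shifted window with a leading zero, so the
        last true value y_{t+L-1} appears nowhere in the inputs."""
        config, params = small
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4)
        window = rng.standard_normal(3)  # (y_t, y_{t+1}, y_{t+2})
        dec = np.concatenate([[0.0], window[:-1]])
        assert window[-1] not in dec
        out = stnn_forward(x, dec, params, config)
        assert out.shape == (3,)

    def test_full_gradient_matches_finite_differences(self, small):
        config, params = small
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4)
        dec = rng.standard_normal(3)
        target = rng.standard_normal(3)
        tensors = params.as_tensors()
        out = stnn_forward(x, dec, tensors, config)
        loss = ad.tsum((out - target) ** 2)
        loss.backward()
        eps = 1e-6
        for name in ("W_FFN", "W_EQ", "W_DK", "W_out", "enc_scale", "b_DFFN"):
            arr = params[name]
            flat_idx = np.unravel_index(
                np.argmax(np.abs(tensors[name].grad)), arr.shape
            )
            for idx in [flat_idx]:
                up, dn = params.copy(), params.copy()
                up[name][idx] += eps
                dn[name][idx] -= eps
                fu = np.sum((stnn_forward(x, dec, up, config) - target) ** 2)
                fd = np.sum((stnn_forward(x, dec, dn, config) - target) ** 2)
                num = (fu - fd) / (2 * eps)
                got = tensors[name].grad[idx]
                assert abs(num - got) / max(abs(num), 1e-8) < 1e-4, name

    def test_deterministic_forward(self, small):
        config, params = small
        x = np.arange(4.0)
        dec = np.arange(3.0)
        a = stnn_forward(x, dec, params, config)
        b = stnn_forward(x, dec, params, config)
        np.testing.assert_array_equal(a, b)

    def test_batched_forward_matches_per_sample(self, small):
        config, params = small
        rng = np.random.default_rng(3)
        xs = rng.standard_normal((6, 4))
        decs = rng.standard_normal((6, 3))
        batched = stnn_forward(xs, decs, params, config)
        for i in range(6):
            np.testing.assert_allclose(
                batched[i], stnn_forward(xs[i], decs[i], params, config), atol=1e-12
            )

    @pytest.mark.parametrize("variant", ["stnn", "stnn_star", "stnn_hash", "stnn_hashhash"])
    def test_variants_run_and_differ_from_base(self, variant):
        config = StnnConfig(D=4, L=3, seed=1, variant=variant)
        params = init_params(config)
        rng = np.random.default_rng(2)
        x, dec = rng.standard_normal(4), rng.standard_normal(3)
        out = stnn_forward(x, dec, params, config)
        assert np.all(np.isfinite(out))
        if variant != "stnn":
            base = stnn_forward(
                x, dec, params, StnnConfig(D=4, L=3, seed=1, variant="stnn")
            )
            assert not np.allclose(out, base)

    def test_checkpoint_round_trip_is_bit_exact(self, small, tmp_path):
        config, params = small
        p = tmp_path / "model.ckpt"
        save_checkpoint(p, params, config)
        params2, config2 = load_checkpoint(p)
        assert config2 == config
        assert set(params2) == set(params)
        for k in params:
            np.testing.assert_array_equal(params[k], params2[k])
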