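"""Convolution, pooling and normalization primitives against direct oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundusnet.nn import Conv2D, BatchNorm, MaxPool2x2, GlobalAveragePool
from fundusnet.ops import depthwise_separable, gap, softmax


def dsconv_oracle(x, dw, pw, dw_b, pw_b):
    """Nested-loop depthwise-then-pointwise convolution with ReLU stages."""
    h, w, c = x.shape
    f = pw.shape[-1]
    ydw = np.zeros((h, w, c))
    for i in range(h):
        for j in range(w):
            for ch in range(c):
                acc = 0.0
                for p in (-1, 0, 1):
                    for q in (-1, 0, 1):
                        ii, jj = i + p, j + q
                        if 0 <= ii < h and 0 <= jj < w:
                            acc += dw[p + 1, q + 1, ch] * x[ii, jj, ch]
                ydw[i, j, ch] = max(acc + dw_b[ch], 0.0)
    out = np.zeros((h, w, f))
    for i in range(h):
        for j in range(w):
            for fo in range(f):
                out[i, j, fo] = max(
                    sum(ydw[i, j, ch] * pw[ch, fo] for ch in range(c)) + pw_b[fo], 0.0
                )
    return out


class TestDepthwiseSeparable:
    def test_zero_kernels_propagate_zero(self, rng):
        x = rng.random((5, 5, 3))
        out = depthwise_separable(
            x, np.zeros((3, 3, 3)), np.zeros((3, 4)), np.zeros(3), np.zeros(4)
        )
        assert out.shape == (5, 5, 4)
        assert np.all(out == 0.0)

    def test_identity_kernels_reduce_to_relu(self, rng):
        c = 2
        x = rng.standard_normal((4, 4, c))
        dw = np.zeros((3, 3, c))
        dw[1, 1, :] = 1.0  # center delta
        pw = np.eye(c)
        out = depthwise_separable(x, dw, pw, np.zeros(c), np.zeros(c))
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.standard_normal((5, 5, 2))
        dw = rng.standard_normal((3, 3, 2))
        pw = rng.standard_normal((2, 3))
        dw_b = rng.standard_normal(2)
        pw_b = rng.standard_normal(3)
        got = depthwise_separable(x, dw, pw, dw_b, pw_b)
        want = dsconv_oracle(x, dw, pw, dw_b, pw_b)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        x = rng.random((4, 4, 3))
        with pytest.raises(ValueError, match="depthwise"):
            depthwise_separable(x, np.zeros((3, 3, 2)), np.zeros((2, 4)))


class TestConvLayer:
    def test_dense_conv_matches_loop(self, rng):
        conv = Conv2D("c", 2, 3, 3, rng=rng)
        x = rng.standard_normal((1, 5, 5, 2))
        got = conv.forward(x)
        k = conv.w.value
        want = np.zeros((5, 5, 3))
        for i in range(5):
            for j in range(5):
                for fo in range(3):
                    acc = conv.b.value[fo]
                    for p in (-1, 0, 1):
                        for q in (-1, 0, 1):
                            ii, jj = i + p, j + q
                            if 0 <= ii < 5 and 0 <= jj < 5:
                                acc += np.dot(k[p + 1, q + 1, :, fo], x[0, ii, jj])
                    want[i, j, fo] = acc
        np.testing.assert_allclose(got[0], want, atol=1e-10)


class TestPoolingAndGap:
    def test_maxpool_floor_semantics(self, rng):
        pool = MaxPool2x2("p")
        assert pool.forward(rng.random((1, 75, 75, 2))).shape == (1, 37, 37, 2)
        assert pool.forward(rng.random((1, 9, 9, 2))).shape == (1, 4, 4, 2)

    def test_maxpool_takes_window_maximum(self):
        x = np.arange(16, dtype=float).reshape(1, 4, 4, 1)
        out = MaxPool2x2("p").forward(x)
        np.testing.assert_array_equal(out[0, :, :, 0], [[5, 7], [13, 15]])

    def test_gap_of_constant_map_is_constant(self):
        x = np.full((6, 5, 3), 2.5)
        x[:, :, 1] = -1.0
        np.testing.assert_allclose(gap(x), [2.5, -1.0, 2.5])

    def test_gap_is_linear(self, rng):
        a, b = rng.random((4, 4, 2)), rng.random((4, 4, 2))
        np.testing.assert_allclose(gap(2.0 * a + 3.0 * b), 2.0 * gap(a) + 3.0 * gap(b))

    def test_gap_layer_backward_spreads_uniformly(self, rng):
        layer = GlobalAveragePool("g")
        x = rng.random((2, 3, 3, 2))
        layer.forward(x)
        dx = layer.backward(np.ones((2, 2)))
        np.testing.assert_allclose(dx, 1.0 / 9.0)


class TestSoftmax:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_normalize(self, seed):
        logits = np.random.default_rng(seed).standard_normal((4, 10)) * 50
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.isfinite(p))

    def test_shift_invariance(self, rng):
        logits = rng.standard_normal((3, 5))
        np.testing.assert_allclose(softmax(logits), softmax(logits + 123.0), atol=1e-12)


class TestBatchNorm:
    def test_inference_uses_moving_statistics(self, rng):
        bn = BatchNorm("bn", 3, eps=1e-3)
        bn.moving_mean.value[...] = [1.0, 2.0, 3.0]
        bn.moving_var.value[...] = [4.0, 4.0, 4.0]
        x = rng.random((2, 4, 4, 3))
        out = bn.forward(x, training=False)
        want = (x - bn.moving_mean.value) / np.sqrt(4.0 + 1e-3)
        np.testing.assert_allclose(out, want)

    def test_training_normalizes_batch(self, rng):
        bn = BatchNorm("bn", 2)
        x = rng.standard_normal((8, 5, 5, 2)) * 3 + 7
        out = bn.forward(x, training=True)
        np.testing.assert_allclose(out.mean(axis=(0, 1, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=(0, 1, 2)), 1.0, atol=1e-2)


class TestResidualFunctional:
    def test_zero_main_path_with_identity_skip_is_identity(self, rng):
        from fundusnet.ops import residual_block

        c = 4
        x = rng.standard_normal((5, 5, c))
        out = residual_block(
            x,
            conv1_kernel=np.zeros((3, 3, c, c)),
            conv2_kernel=np.zeros((3, 3, c, c)),
            skip_kernel=np.eye(c),
        )
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_output_shape_at_full_width(self, rng):
        from fundusnet.ops import residual_block

        x = rng.standard_normal((9, 9, 512)) * 0.01
        out = residual_block(
            x,
            conv1_kernel=rng.standard_normal((3, 3, 512, 1024)) * 0.01,
            conv2_kernel=rng.standard_normal((3, 3, 1024, 1024)) * 0.01,
            skip_kernel=rng.standard_normal((512, 1024)) * 0.01,
        )
        assert out.shape == (9, 9, 1024)
        assert np.all(np.isfinite(out))
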