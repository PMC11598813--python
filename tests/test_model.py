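"""Binary network primitives against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bdscnn import (BNParams, DEFAULT_CONFIG, ModelConfig, binarize,
                    bconv_valid, count_params_and_ops, dsc_forward, forward,
                    or_maxpool, random_weights)


def _conv_oracle(image, kernel, stride=1):
    kh, kw = kernel.shape
    oh = (image.shape[0] - kh) // stride + 1
    ow = (image.shape[1] - kw) // stride + 1
    out = np.zeros((oh, ow), dtype=np.int64)
    for r in range(oh):
        for c in range(ow):
            for a in range(kh):
                for b in range(kw):
                    out[r, c] += image[r * stride + a, c * stride + b] * kernel[a, b]
    return out


def _pool_oracle(bits, P, SP):
    oh = (bits.shape[0] - P) // SP + 1
    ow = (bits.shape[1] - P) // SP + 1
    out = np.zeros((oh, ow), dtype=np.uint8)
    for r in range(oh):
        for c in range(ow):
            out[r, c] = bits[r * SP : r * SP + P, c * SP : c * SP + P].max()
    return out


@pytest.mark.parametrize("x,expected", [(0.5, 1), (0, 0), (-2, 0), (3, 1)])
def test_binarize_threshold_at_zero(x, expected):
    assert binarize(x) == expected


@given(st.floats(allow_nan=False, allow_infinity=False))
def test_binarize_idempotent(x):
    assert binarize(binarize(x)) == binarize(x)


class TestBConv:
    def test_default_geometry_30x30(self, rng):
        img = rng.integers(0, 2, (32, 32))
        assert bconv_valid(img, rng.integers(0, 2, (3, 3))).shape == (30, 30)

    def test_zero_kernel_annihilates(self, rng):
        img = rng.integers(0, 2, (8, 8))
        assert bconv_valid(img, np.zeros((3, 3), int)).sum() == 0

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(25):
            img = rng.integers(0, 2, (5, 5))
            ker = rng.integers(0, 2, (3, 3))
            np.testing.assert_array_equal(bconv_valid(img, ker),
                                          _conv_oracle(img, ker))

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger than image"):
            bconv_valid(np.zeros((2, 2)), np.ones((3, 3)))

    def test_exhaustive_4x4_against_oracle(self):
        """All 2^16 4x4 binary images, fixed kernel, vs the nested-loop oracle."""
        imgs = ((np.arange(65536)[:, None] >> np.arange(16)) & 1).reshape(-1, 4, 4)
        ker = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
        win = np.lib.stride_tricks.sliding_window_view(imgs, (3, 3), axis=(1, 2))
        fast = np.einsum("nxyab,ab->nxy", win, ker)
        for n in (0, 1, 37, 65535, 21845):
            np.testing.assert_array_equal(fast[n], _conv_oracle(imgs[n], ker))
        # and OR-pooling the binarized maps matches the max-filter oracle
        pooled_fast = (fast > 0).reshape(-1, 1, 2, 1, 2).max(axis=(2, 4))
        for n in (0, 1, 37, 65535, 21845):
            np.testing.assert_array_equal(
                pooled_fast[n], _pool_oracle((fast[n] > 0).astype(np.uint8), 2, 2))


class TestOrMaxpool:
    def test_default_geometry_15x15(self, rng):
        assert or_maxpool(rng.integers(0, 2, (30, 30))).shape == (15, 15)

    def test_all_ones_fixed_point(self):
        np.testing.assert_array_equal(or_maxpool(np.ones((4, 4), int)),
                                      np.ones((2, 2)))

    def test_matches_max_filter_oracle(self, rng):
        for _ in range(25):
            bits = rng.integers(0, 2, (10, 10))
            np.testing.assert_array_equal(or_maxpool(bits, 2, 2),
                                          _pool_oracle(bits, 2, 2))


class TestDSC:
    def test_default_shapes_13x13x18(self, rng):
        w = random_weights(seed=3)
        maps = rng.integers(0, 2, (15, 15, 3)).astype(np.uint8)
        out = dsc_forward(maps, w.dw, w.pw, w.bn_dsc)
        assert out.shape == (13, 13, 18)
        assert set(np.unique(out)) <= {0, 1}

    def test_zero_pw_channel_is_constant(self, rng):
        w = random_weights(seed=3)
        pw = w.pw.copy()
        pw[0] = 0
        maps = rng.integers(0, 2, (15, 15, 3)).astype(np.uint8)
        out = dsc_forward(maps, w.dw, pw, w.bn_dsc)
        expected = binarize(w.bn_dsc.apply(np.zeros(18))[0])
        assert np.all(out[:, :, 0] == expected)

    def test_presums_equal_rank1_conventional_convolution(self, rng):
        """DSC == conventional 3D convolution with kernels dw (x) pw."""
        w = random_weights(seed=5)
        maps = rng.integers(0, 2, (15, 15, 3)).astype(np.uint8)
        _, presum = dsc_forward(maps, w.dw, w.pw, w.bn_dsc, return_presum=True)
        for p in range(18):
            direct = np.zeros((13, 13), dtype=np.int64)
            for k in range(3):
                # rank-1 factored kernel: pw[p,k] * dw[k]
                direct += _conv_oracle(maps[:, :, k],
                                       w.pw[p, k].astype(np.int64) * w.dw[k])
            np.testing.assert_array_equal(presum[:, :, p], direct)

    def test_channel_mismatch_rejected(self, rng):
        w = random_weights(seed=3)
        with pytest.raises(ValueError, match="channel count"):
            dsc_forward(rng.integers(0, 2, (15, 15, 4)), w.dw, w.pw, w.bn_dsc)


class TestForward:
    def test_softmax_five_scores_sum_to_one(self, rng):
        w = random_weights(seed=7)
        scores, label = forward(rng.integers(0, 2, (32, 32)),
                                rng.integers(0, 2, 4), w)
        assert scores.shape == (5,)
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0 <= label < 5

    def test_pure_function_of_inputs(self, rng):
        w = random_weights(seed=7)
        img = rng.integers(0, 2, (32, 32))
        rr = rng.integers(0, 2, 4)
        s1, l1 = forward(img, rr, w)
        s2, l2 = forward(img, rr, w)
        np.testing.assert_array_equal(s1, s2)
        assert l1 == l2

    def test_shape_mismatch_rejected(self, rng):
        w = random_weights(seed=7)
        with pytest.raises(ValueError):
            forward(rng.integers(0, 2, (31, 31)), rng.integers(0, 2, 4), w)


class TestCosts:
    def test_dsc_parameter_reduction_is_6x_at_18_channels(self):
        # per input channel: 9*N conventional vs 9+N separable
        N = 18
        assert (9 * N) / (9 + N) == 6

    def test_published_cost_table(self):
        dsc = count_params_and_ops(DEFAULT_CONFIG, "dsc")
        conv = count_params_and_ops(DEFAULT_CONFIG, "conventional")
        assert dsc["coperation"] == 13_689
        assert conv["coperation"] == 82_134
        assert dsc["kernel_params"] == 108
        assert dsc["kernel_count"] == 24

    def test_scaling_in_pointwise_channels(self):
        """Conventional cost grows ~KP-fold faster than separable."""
        cfg = ModelConfig(KP=36)
        dsc = count_params_and_ops(cfg, "dsc")
        conv = count_params_and_ops(cfg, "conventional")
        assert conv["coperation"] / dsc["coperation"] > 4


def test_bn_params_validation():
    with pytest.raises(ValueError, match="sigma"):
        BNParams(gamma=1.0, beta=0.0, mu=0.0, sigma=-1.0)
    with pytest.raises(ValueError, match="eps"):
        BNParams(gamma=1.0, beta=0.0, mu=0.0, sigma=1.0, eps=0.0)
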