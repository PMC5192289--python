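"""Layer primitives: forward definitions against brute-force oracles,
backward passes against central differences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import pool_oracle

from nodulefpr import tensor_core as tc


# ---------------------------------------------------------------------------
# convolution forward
# ---------------------------------------------------------------------------

class TestConvForward:
    def test_shape_chain_matches_first_stage(self, rng):
        """1x32x32 through 8 kernels of 1x5x5 yields 8x28x28 = 6272 units."""
        x = rng.uniform(0, 1, (1, 32, 32))
        k = rng.normal(size=(8, 1, 5, 5))
        y = tc.conv_forward(x, k, np.zeros(8))
        assert y.shape == (8, 28, 28)
        assert y.size == 6272

    def test_zero_input_gives_bias_maps(self, rng):
        k = rng.normal(size=(3, 2, 5, 5))
        b = rng.normal(size=3)
        y = tc.conv_forward(np.zeros((2, 12, 12)), k, b)
        for o in range(3):
            np.testing.assert_allclose(y[o], b[o])

    @pytest.mark.parametrize("shape,kshape,stride", [
        ((1, 6, 6), (2, 1, 3, 3), 1),
        ((3, 9, 7), (4, 3, 3, 3), 2),
        ((2, 10, 10), (5, 2, 5, 5), 1),
        ((1, 8, 8), (1, 1, 2, 2), 2),
    ])
    def test_matches_nested_loop_oracle(self, rng, conv_loop_oracle,
                                        shape, kshape, stride):
        x = rng.normal(size=shape)
        k = rng.normal(size=kshape)
        b = rng.normal(size=kshape[0])
        np.testing.assert_allclose(tc.conv_forward(x, k, b, stride=stride),
                                   conv_loop_oracle(x, k, b, stride=stride),
                                   atol=1e-12)

    def test_linearity_in_input(self, rng):
        k = rng.normal(size=(2, 1, 3, 3))
        b = np.zeros(2)
        x1, x2 = rng.normal(size=(2, 1, 6, 6))
        lhs = tc.conv_forward(2.0 * x1 + 3.0 * x2, k, b)
        rhs = 2.0 * tc.conv_forward(x1, k, b) + 3.0 * tc.conv_forward(x2, k, b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            tc.conv_forward(rng.normal(size=(2, 6, 6)),
                            rng.normal(size=(1, 3, 3, 3)), np.zeros(1))

    def test_non_integer_output_dim_rejected(self, rng):
        with pytest.raises(ValueError, match="non-integer"):
            tc.conv_forward(rng.normal(size=(1, 7, 7)),
                            rng.normal(size=(1, 1, 2, 2)), np.zeros(1), stride=2)


# ---------------------------------------------------------------------------
# ReLU
# ---------------------------------------------------------------------------

class TestRelu:
    def test_definition(self):
        x = np.array([[-1.0, 0.0, 2.5]])
        np.testing.assert_array_equal(tc.relu(x), [[0.0, 0.0, 2.5]])
        assert tc.relu(-np.ones((2, 3))).sum() == 0.0

    @given(arrays(np.float64, (3, 4), elements=st.floats(-10, 10)))
    def test_idempotent_and_nonnegative(self, x):
        once = tc.relu(x)
        assert (once >= 0).all()
        np.testing.assert_array_equal(tc.relu(once), once)


# ---------------------------------------------------------------------------
# max pooling
# ---------------------------------------------------------------------------

class TestMaxpool:
    def test_second_stage_unit_count(self, rng):
        y, _ = tc.maxpool_forward(rng.normal(size=(8, 28, 28)))
        assert y.shape == (8, 14, 14)
        assert y.size == 1568

    def test_constant_input_preserved(self):
        y, _ = tc.maxpool_forward(np.full((2, 4, 4), 3.25))
        np.testing.assert_array_equal(y, np.full((2, 2, 2), 3.25))

    @given(arrays(np.float64, (1, 4, 4), elements=st.floats(-5, 5)))
    def test_matches_exhaustive_window_max(self, x):
        y, record = tc.maxpool_forward(x)
        np.testing.assert_array_equal(y, pool_oracle(x))
        assert ((record.offsets >= 0) & (record.offsets < 2)).all()

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            tc.maxpool_forward(rng.normal(size=(1, 5, 4)))

    @given(arrays(np.float64, (2, 6, 6), elements=st.floats(-5, 5, allow_nan=False)))
    def test_backward_conserves_gradient_mass(self, x):
        _, record = tc.maxpool_forward(x)
        g = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3)
        gx = tc.maxpool_backward(g, record)
        assert gx.shape == x.shape
        np.testing.assert_allclose(gx.sum(), g.sum(), atol=1e-12)

    def test_tie_routes_to_first_row_major_cell(self):
        x = np.full((1, 2, 2), 1.0)  # four-way tie in the single window
        _, record = tc.maxpool_forward(x)
        gx = tc.maxpool_backward(np.array([[[5.0]]]), record)
        np.testing.assert_array_equal(gx, [[[5.0, 0.0], [0.0, 0.0]]])


# ---------------------------------------------------------------------------
# fully connected
# ---------------------------------------------------------------------------

class TestFc:
    def test_identity_and_bias_cases(self, rng):
        x = rng.normal(size=4)
        np.testing.assert_allclose(tc.fc_forward(x, np.eye(4), np.zeros(4)), x)
        b = rng.normal(size=3)
        np.testing.assert_allclose(tc.fc_forward(x, np.zeros((3, 4)), b), b)

    def test_matches_hand_expanded_dot_products(self):
        w = np.array([[1.0, 2.0, 3.0], [-1.0, 0.5, 4.0]])
        x = np.array([2.0, -1.0, 0.5])
        b = np.array([0.1, -0.2])
        expected = np.array([1 * 2 + 2 * -1 + 3 * 0.5 + 0.1,
                             -1 * 2 + 0.5 * -1 + 4 * 0.5 - 0.2])
        np.testing.assert_allclose(tc.fc_forward(x, w, b), expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            tc.fc_forward(rng.normal(size=5), rng.normal(size=(2, 4)), np.zeros(2))


# ---------------------------------------------------------------------------
# softmax + cross-entropy
# ---------------------------------------------------------------------------

class TestSoftmaxCrossEntropy:
    def test_symmetry_and_direct_formula(self):
        np.testing.assert_allclose(tc.softmax(np.zeros(2)), [0.5, 0.5])
        z = np.array([1.0, 2.0])
        direct = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(tc.softmax(z), direct, rtol=1e-12)

    @given(arrays(np.float64, (2,), elements=st.floats(-50, 50)),
           st.floats(-100, 100))
    def test_normalized_and_shift_invariant(self, z, c):
        p = tc.softmax(z)
        assert abs(p.sum() - 1.0) < 1e-12
        assert ((p > 0) & (p < 1)).all() or p.max() <= 1.0
        np.testing.assert_allclose(tc.softmax(z + c), p, atol=1e-12)

    def test_extreme_logits_stay_finite(self):
        p = tc.softmax(np.array([1000.0, -1000.0]))
        assert np.isfinite(p).all()
        assert abs(p.sum() - 1.0) < 1e-12

    def test_loss_closed_forms(self, rng):
        assert tc.cross_entropy_loss(np.array([1.0, 0.0]), 0) <= 1e-9
        np.testing.assert_allclose(tc.cross_entropy_loss(np.array([0.5, 0.5]), 1),
                                   np.log(2.0), rtol=1e-12)
        p = rng.dirichlet(np.ones(2))
        np.testing.assert_allclose(tc.cross_entropy_loss(p, 1), -np.log(p[1]),
                                   rtol=1e-12)

    def test_combined_backward_is_probs_minus_onehot(self):
        np.testing.assert_allclose(
            tc.softmax_ce_backward(np.array([0.5, 0.5]), 1), [0.5, -0.5])
        batch = np.array([[0.9, 0.1], [0.2, 0.8]])
        grad = tc.softmax_ce_backward(batch, np.array([0, 1]))
        np.testing.assert_allclose(grad, [[-0.1, 0.1], [0.2, -0.2]])


# ---------------------------------------------------------------------------
# backward passes vs central differences
# ---------------------------------------------------------------------------

class TestGradients:
    def test_zero_upstream_gives_zero_parameter_grads(self, rng):
        x = rng.normal(size=(2, 6, 6))
        k = rng.normal(size=(3, 2, 3, 3))
        _, gk, gb = tc.conv_backward(np.zeros((3, 4, 4)), x, k)
        assert not gk.any() and not gb.any()

    def test_missing_cache_rejected(self):
        with pytest.raises(ValueError):
            tc.conv_backward(np.zeros((1, 2, 2)), None, None)
        with pytest.raises(ValueError):
            tc.fc_backward(np.zeros(2), None, None)
        with pytest.raises(ValueError):
            tc.maxpool_backward(np.zeros((1, 1, 1)), None)

    def test_linear_fc_gradient_is_exact(self, rng):
        x = rng.normal(size=4)
        w = rng.normal(size=(3, 4))
        gy = rng.normal(size=3)
        gx, gw, gb = tc.fc_backward(gy, x, w)
        num = tc.numeric_gradient(lambda a: float(tc.fc_forward(a, w, np.zeros(3)) @ gy),
                                  x.copy())
        assert tc.relative_deviation(gx, num) < 1e-9

    @pytest.mark.parametrize("stride", [1, 2])
    def test_conv_backward_matches_central_differences(self, rng, stride):
        x = rng.normal(size=(2, 7, 7))
        k = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        gy = rng.normal(size=tc.conv_forward(x, k, b, stride=stride).shape)
        gx, gk, gb = tc.conv_backward(gy, x, k, stride=stride)

        def proj(arrs):
            return float(np.sum(tc.conv_forward(arrs["x"], arrs["k"], arrs["b"],
                                                stride=stride) * gy))

        dev = tc.numeric_gradient_check(proj, {"x": x, "k": k, "b": b},
                                        {"x": gx, "k": gk, "b": gb})
        assert dev < 1e-5

    def test_maxpool_backward_matches_central_differences(self, rng):
        # ties are measure-zero for continuous draws; perturb well below gaps
        x = rng.normal(size=(2, 6, 6))
        y, record = tc.maxpool_forward(x)
        gy = rng.normal(size=y.shape)
        gx = tc.maxpool_backward(gy, record)
        num = tc.numeric_gradient(
            lambda a: float(np.sum(tc.maxpool_forward(a)[0] * gy)), x.copy(),
            eps=1e-6)
        assert tc.relative_deviation(gx, num, eps=1e-6) < 1e-5

    def test_relu_backward_matches_central_differences(self, rng):
        x = rng.normal(size=(3, 5)) + np.sign(rng.normal(size=(3, 5))) * 0.05
        gy = rng.normal(size=(3, 5))
        gx = tc.relu_backward(gy, x)
        num = tc.numeric_gradient(lambda a: float(np.sum(tc.relu(a) * gy)),
                                  x.copy(), eps=1e-6)
        assert tc.relative_deviation(gx, num, eps=1e-6) < 1e-5

    def test_softmax_ce_backward_matches_central_differences(self, rng):
        z = rng.normal(size=2)
        label = 1
        grad = tc.softmax_ce_backward(tc.softmax(z), label)
        num = tc.numeric_gradient(
            lambda a: tc.cross_entropy_loss(tc.softmax(a), label), z.copy())
        assert tc.relative_deviation(grad, num) < 1e-5
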