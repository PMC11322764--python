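import math

import numpy as np
import pytest

from mdlink._autograd import Tensor
from mdlink.csae import (
    AttributeMatrix,
    CsaeConfig,
    _forward_graph,
    _im2col_const,
    assemble_attribute_matrix,
    conv_decode,
    conv_encode,
    csae_loss,
    flatten_channels,
    linear_decode,
    linear_encode,
    partition_channels,
    sparsity_penalty,
    train_csae,
)

SIG1 = 1 / (1 + math.exp(-1))  # 0.73106


# -- nested-loop convolution oracles --------------------------------------


def conv_encode_oracle(AX, kernels, bias):
    nr, nc = AX.shape
    channels = kernels.shape[2]
    out = np.zeros((nr, nc, channels))
    for c in range(channels):
        for p in range(nr):
            for q in range(nc):
                acc = bias[c]
                for u in range(3):
                    for v in range(3):
                        pp, qq = p + u - 1, q + v - 1
                        if 0 <= pp < nr and 0 <= qq < nc:
                            acc += AX[pp, qq] * kernels[u, v, c]
                out[p, q, c] = max(acc, 0.0)
    return out


def conv_decode_oracle(y, channels, kernel, bias):
    """Scatter form of the transposed convolution."""
    f = partition_channels(y, channels)
    nr, nc, _ = f.shape
    out = np.full((nr, nc), float(bias))
    for c in range(channels):
        for p in range(nr):
            for q in range(nc):
                for du in (-1, 0, 1):
                    for dv in (-1, 0, 1):
                        pp, qq = p + du, q + dv
                        if 0 <= pp < nr and 0 <= qq < nc:
                            out[pp, qq] += f[p, q, c] * kernel[1 + du, 1 + dv, c]
    return np.maximum(out, 0.0)


class TestAssemble:
    def test_disease_shape(self):
        A = np.zeros((2, 3))
        AD = assemble_attribute_matrix(A, np.eye(2), np.eye(2), np.eye(2), "disease")
        assert AD.values.shape == (2, 9)  # Nm + 3 Nd

    def test_block_roundtrip(self):
        rng = np.random.default_rng(0)
        A = (rng.random((3, 4)) < 0.5).astype(float)
        cos = rng.random((3, 3))
        AD = assemble_attribute_matrix(A, np.eye(3), cos, np.eye(3), "disease")
        assert np.array_equal(AD.block("SDCOS"), cos)
        assert np.array_equal(AD.block("A"), A)

    def test_microbe_shape_at_hmdad_scale(self):
        A = np.zeros((39, 292))
        z = np.zeros((292, 292))
        AM = assemble_attribute_matrix(A, z, z, z, "microbe")
        assert AM.values.shape == (292, 39 + 3 * 292)

    def test_dimension_mismatch_names_block(self):
        with pytest.raises(ValueError, match="SDMM"):
            assemble_attribute_matrix(np.zeros((2, 3)), np.eye(3), np.eye(2),
                                      np.eye(2), "disease")


class TestConvEncode:
    def test_zero_kernels(self):
        out = conv_encode(np.ones((4, 5)), np.zeros((3, 3, 2)), np.zeros(2))
        assert np.array_equal(out, np.zeros((4, 5, 2)))

    def test_identity_kernel_passthrough(self):
        k = np.zeros((3, 3, 1))
        k[1, 1, 0] = 1.0
        x = np.abs(np.random.default_rng(0).standard_normal((4, 6)))
        out = conv_encode(x, k, np.zeros(1))
        assert np.allclose(out[:, :, 0], x)

    def test_all_ones_hand_example(self):
        out = conv_encode(np.ones((3, 3)), np.ones((3, 3, 1)), np.zeros(1))[:, :, 0]
        assert out[1, 1] == 9
        assert out[0, 0] == out[0, 2] == out[2, 0] == out[2, 2] == 4
        assert out[0, 1] == out[1, 0] == out[1, 2] == out[2, 1] == 6

    @pytest.mark.parametrize("channels", [1, 3, 6])
    def test_matches_nested_loop_oracle(self, channels):
        rng = np.random.default_rng(channels)
        x = rng.standard_normal((5, 7))
        k = rng.standard_normal((3, 3, channels))
        b = rng.standard_normal(channels)
        assert np.allclose(conv_encode(x, k, b), conv_encode_oracle(x, k, b), atol=1e-12)


class TestFlattenPartition:
    def test_documented_order_and_inverse(self):
        fX = np.arange(2 * 2 * 2, dtype=float).reshape(2, 2, 2)
        ft = flatten_channels(fX)
        # row i = [channel-0 row | channel-1 row]
        assert np.array_equal(ft[0], [fX[0, 0, 0], fX[0, 1, 0], fX[0, 0, 1], fX[0, 1, 1]])
        assert np.array_equal(partition_channels(ft, 2), fX)

    def test_roundtrip_random(self):
        rng = np.random.default_rng(1)
        fX = rng.standard_normal((3, 5, 4))
        assert np.array_equal(partition_channels(flatten_channels(fX), 4), fX)

    def test_indivisible_columns_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            partition_channels(np.zeros((2, 7)), 2)


class TestLinearLayers:
    def test_zero_weights_give_half(self):
        fX = np.ones((3, 4, 2))
        h = linear_encode(fX, np.zeros((8, 5)), np.zeros(5))
        assert np.allclose(h, 0.5)
        y = linear_decode(h, np.zeros((5, 8)), np.zeros(8))
        assert np.allclose(y, 0.5)
        assert y.shape == (3, 8)

    def test_unit_preactivation(self):
        fX = np.ones((1, 1, 1))
        W = np.array([[1.0]])
        h = linear_encode(fX, W, np.zeros(1))
        assert h[0, 0] == pytest.approx(SIG1, abs=1e-5)
        y = linear_decode(np.array([[0.0]]), np.array([[-1.0]]), np.zeros(1))
        # pre-activation -1 ... via bias instead
        y = linear_decode(np.array([[1.0]]), np.array([[-1.0]]), np.zeros(1))
        assert y[0, 0] == pytest.approx(1 - SIG1, abs=1e-5)


class TestConvDecode:
    def test_zero_input(self):
        out = conv_decode(np.zeros((2, 6)), 2, np.ones((3, 3, 2)), 0.0)
        assert np.array_equal(out, np.zeros((2, 3)))

    def test_single_channel_center_kernel_passthrough(self):
        k = np.zeros((3, 3, 1))
        k[1, 1, 0] = 1.0
        y = np.abs(np.random.default_rng(0).standard_normal((3, 4)))
        assert np.allclose(conv_decode(y, 1, k, 0.0), y)

    def test_row_vector_hand_example(self):
        out = conv_decode(np.array([[1.0, 0.0, 0.0]]), 1, np.ones((3, 3, 1)), 0.0)
        assert np.array_equal(out, [[1.0, 1.0, 0.0]])

    @pytest.mark.parametrize("channels", [1, 2, 4])
    def test_matches_scatter_oracle(self, channels):
        rng = np.random.default_rng(channels + 5)
        y = rng.standard_normal((4, 6 * channels))
        k = rng.standard_normal((3, 3, channels))
        b = rng.standard_normal()
        assert np.allclose(
            conv_decode(y, channels, k, b), conv_decode_oracle(y, channels, k, b),
            atol=1e-12,
        )


class TestSparsityPenalty:
    def test_zero_at_target(self):
        h = np.full((10, 4), 0.05)
        assert sparsity_penalty(h, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_value(self):
        # single unit with mean activation 0.5 against target 0.05
        h = np.full((2, 1), 0.5)
        expected = 0.05 * math.log(0.1) + 0.95 * math.log(1.9)
        assert sparsity_penalty(h, 0.05) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.49463, abs=1e-5)

    def test_nonnegative_and_clamps(self):
        rng = np.random.default_rng(0)
        h = rng.random((8, 5))
        assert sparsity_penalty(h, 0.05) >= 0
        with pytest.warns(RuntimeWarning, match="clamp"):
            sparsity_penalty(np.ones((3, 2)), 0.05)


class TestLoss:
    def test_perfect_reconstruction(self):
        x = np.random.default_rng(0).random((3, 4))
        h = np.full((3, 2), 0.05)
        assert csae_loss(x, x, h, beta=0.1, rho=0.05) == pytest.approx(0.0, abs=1e-12)

    def test_beta_zero_is_row_mean_mse(self):
        AX = np.zeros((1, 2))
        rec = np.array([[0.1, 0.2]])
        h = np.random.default_rng(0).random((1, 3))
        assert csae_loss(rec, AX, h, beta=0.0, rho=0.05) == pytest.approx(0.05)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            csae_loss(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 1)), 0.1, 0.05)


def _training_params_to_reference(params, channels, nc):
    """Map training-layout parameters to the reference channel-major layout."""
    perm = np.array([j * channels + c for c in range(channels) for j in range(nc)])
    return {
        "kernels": np.asarray(params["K_enc"].data, dtype=float).reshape(3, 3, channels),
        "b_enc": np.asarray(params["b_enc"].data, dtype=float),
        "W_enc": np.asarray(params["W_enc"].data, dtype=float)[perm],
        "B_enc": np.asarray(params["B_enc"].data, dtype=float),
        "W_dec": np.asarray(params["W_dec"].data, dtype=float)[:, perm],
        "B_dec": np.asarray(params["B_dec"].data, dtype=float)[perm],
        "K_dec": np.asarray(params["K_dec"].data, dtype=float).reshape(3, 3, channels),
        "b_dec": float(params["b_dec"].data),
    }


class TestTraining:
    def _toy_matrix(self, nr=6, nc_extra=4, seed=0):
        rng = np.random.default_rng(seed)
        A = (rng.random((nr, nc_extra)) < 0.4).astype(float)
        sim = rng.random((nr, nr))
        sim = (sim + sim.T) / 2
        return assemble_attribute_matrix(A, sim, sim, np.eye(nr), "disease")

    def test_untrained_embedding_deterministic_and_shaped(self):
        AD = self._toy_matrix()
        cfg = CsaeConfig(k2=32, channels=3, epochs=0, seed=9)
        e1 = train_csae(AD, cfg)
        e2 = train_csae(AD, cfg)
        assert np.array_equal(e1.values, e2.values)
        assert e1.values.shape == (6, 32)
        assert (e1.values > 0).all() and (e1.values < 1).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_training_reduces_loss(self, seed):
        AD = self._toy_matrix(seed=seed)
        e = train_csae(AD, CsaeConfig(k2=4, channels=2, epochs=60, lr2=0.01, seed=seed))
        assert e.loss_trace[-1] < e.loss_trace[0]

    def test_training_graph_matches_reference_ops(self):
        """The autodiff forward equals the documented reference pipeline
        once the fixed channel-order column permutation is applied."""
        AD = self._toy_matrix()
        cfg = CsaeConfig(k2=5, channels=3, epochs=0, seed=2, dtype="float64")
        # build params exactly as train_csae does
        import mdlink.csae as m

        values = AD.values.astype(np.float64)
        nr, nc = values.shape
        rng = np.random.default_rng(2)
        params = {
            "K_enc": Tensor(m._xavier(rng, 9, 27, (9, 3), np.float64)),
            "b_enc": Tensor(np.zeros(3)),
            "W_enc": Tensor(m._xavier(rng, 3 * nc, 5, (3 * nc, 5), np.float64)),
            "B_enc": Tensor(np.zeros(5)),
            "W_dec": Tensor(m._xavier(rng, 5, 3 * nc, (5, 3 * nc), np.float64)),
            "B_dec": Tensor(np.zeros(3 * nc)),
            "K_dec": Tensor(m._xavier(rng, 27, 9, (9, 3), np.float64)),
            "b_dec": Tensor(np.zeros(())),
        }
        h_t, F_t = _forward_graph(Tensor(_im2col_const(values)), params, nr, nc, 3)
        ref = _training_params_to_reference(params, 3, nc)
        fX = conv_encode(values, ref["kernels"], ref["b_enc"])
        h = linear_encode(fX, ref["W_enc"], ref["B_enc"])
        y = linear_decode(h, ref["W_dec"], ref["B_dec"])
        F = conv_decode(y, 3, ref["K_dec"], ref["b_dec"])
        assert np.allclose(h_t.data, h, atol=1e-12)
        assert np.allclose(F_t.data, F, atol=1e-12)

    def test_gradient_matches_finite_differences(self):
        """Full sparse-loss gradient vs central differences on a tiny model."""
        rng = np.random.default_rng(4)
        values = rng.random((3, 4))
        nr, nc = values.shape
        channels, k2, beta, rho = 2, 3, 0.1, 0.05
        shapes = {
            "K_enc": (9, channels), "b_enc": (channels,),
            "W_enc": (channels * nc, k2), "B_enc": (k2,),
            "W_dec": (k2, channels * nc), "B_dec": (channels * nc,),
            "K_dec": (9, channels), "b_dec": (),
        }
        arrays = {k: rng.standard_normal(s) * 0.3 for k, s in shapes.items()}
        patches = Tensor(_im2col_const(values))
        target = Tensor(values)

        def loss_value(arrs):
            params = {k: Tensor(v) for k, v in arrs.items()}
            h, F = _forward_graph(patches, params, nr, nc, channels)
            mse = ((F - target) ** 2).sum() / nr
            rho_hat = h.mean(axis=0).clip(1e-8, 1 - 1e-8)
            kl = (rho * (rho / rho_hat).log()
                  + (1 - rho) * ((1 - rho) / (1 - rho_hat)).log()).sum()
            return mse + beta * kl

        params = {k: Tensor(v.copy(), requires_grad=True) for k, v in arrays.items()}
        h, F = _forward_graph(patches, params, nr, nc, channels)
        mse = ((F - target) ** 2).sum() / nr
        rho_hat = h.mean(axis=0).clip(1e-8, 1 - 1e-8)
        kl = (rho * (rho / rho_hat).log()
              + (1 - rho) * ((1 - rho) / (1 - rho_hat)).log()).sum()
        loss = mse + beta * kl
        loss.backward()

        eps = 1e-6
        for name in shapes:
            base = arrays[name]
            num = np.zeros_like(base, dtype=float)
            it = np.nditer(np.atleast_1d(base), flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index if base.ndim else ()
                orig = base[idx] if base.ndim else float(base)
                trial = {k: v.copy() for k, v in arrays.items()}
                if base.ndim:
                    trial[name][idx] = orig + eps
                else:
                    trial[name] = np.asarray(orig + eps)
                hi = float(loss_value(trial).data)
                if base.ndim:
                    trial[name][idx] = orig - eps
                else:
                    trial[name] = np.asarray(orig - eps)
                lo = float(loss_value(trial).data)
                if base.ndim:
                    num[idx] = (hi - lo) / (2 * eps)
                else:
                    num = np.asarray((hi - lo) / (2 * eps))
                it.iternext()
            auto = params[name].grad
            denom = max(np.abs(num).max(), np.abs(auto).max(), 1e-8)
            assert np.abs(auto - num).max() / denom < 1e-4, name

    def test_shape_round_trip_through_all_stages(self):
        """conv -> flatten -> bottleneck -> expand -> deconv restores shape."""
        rng = np.random.default_rng(0)
        for nr, nc, channels, k2 in [(3, 5, 2, 4), (4, 7, 3, 2), (2, 9, 6, 8)]:
            x = rng.random((nr, nc))
            kernels = rng.standard_normal((3, 3, channels))
            fX = conv_encode(x, kernels, np.zeros(channels))
            assert fX.shape == (nr, nc, channels)
            h = linear_encode(fX, rng.standard_normal((nc * channels, k2)), np.zeros(k2))
            assert h.shape == (nr, k2)
            y = linear_decode(h, rng.standard_normal((k2, nc * channels)),
                              np.zeros(nc * channels))
            F = conv_decode(y, channels, rng.standard_normal((3, 3, channels)), 0.0)
            assert F.shape == x.shape
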