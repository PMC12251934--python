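"""Encoder blocks: normalization, SiLU, the SSM scan and its gradients."""

import numpy as np
import pytest

from vimsa import autodiff as ad
from vimsa.encoder import (DirectionPath, Encoder, EncoderBlock, EncoderConfig,
                           SSMParams, layer_norm, silu, ssm_scan,
                           ssm_scan_selective)


class TestLayerNorm:
    def test_constant_token_maps_to_zero(self):
        x = np.full((2, 3, 5), 7.0)
        np.testing.assert_allclose(layer_norm(x), 0.0, atol=1e-3)

    def test_standardizes_features(self, rng):
        out = layer_norm(rng.normal(size=(4, 6, 32)) * 5 + 2)
        assert np.max(np.abs(out.mean(axis=-1))) < 1e-6
        assert np.max(np.abs(out.var(axis=-1) - 1)) < 1e-4

    def test_scale_invariance(self, rng):
        x = rng.normal(size=(2, 3, 16))
        np.testing.assert_allclose(layer_norm(x, eps=1e-12),
                                   layer_norm(10 * x, eps=1e-12), atol=1e-6)


class TestSiLU:
    def test_values(self):
        assert silu(np.array(0.0)) == 0.0
        assert silu(np.array(1.0)) == pytest.approx(0.731059, abs=1e-6)
        assert abs(silu(np.array(-20.0))) < 1e-7

    def test_approaches_identity_for_large_x(self):
        assert silu(np.array(30.0)) == pytest.approx(30.0, abs=1e-10)


class TestSSMScan:
    def test_zero_input_stays_zero(self, rng):
        y = ssm_scan(np.zeros((2, 5, 3)), rng.uniform(size=(2, 5, 3, 4)),
                     rng.normal(size=(2, 5, 3, 4)), rng.normal(size=(2, 5, 4)))
        np.testing.assert_array_equal(y, 0.0)

    def test_hand_unrolled_scalar_recurrence(self):
        y = ssm_scan([1.0, 1.0, 1.0], 0.5, 1.0, 1.0)
        np.testing.assert_allclose(y, [1.0, 1.5, 1.75], atol=1e-15)

    def test_fused_scan_matches_sequential_reference(self, rng):
        for B, J, H, S in [(1, 3, 2, 1), (4, 128, 32, 16), (2, 17, 8, 5)]:
            params = SSMParams(H, S, rng)
            x = ad.Tensor(rng.normal(size=(B, J, H)))
            fused = ssm_scan_selective(x, params).data
            ref = ssm_scan(x.data, *params.discretize(x.data))
            assert np.max(np.abs(fused - ref)) < 1e-6

    def test_transition_matrix_strictly_inside_unit_interval(self, rng):
        params = SSMParams(6, 4, rng)
        Ad, _, _ = params.discretize(rng.normal(size=(2, 9, 6)) * 5)
        assert np.all(Ad > 0) and np.all(Ad < 1)

    def test_non_finite_parameters_raise_with_timestep(self, rng):
        params = SSMParams(3, 2, rng)
        x = ad.Tensor(np.zeros((1, 4, 3)))
        x.data[0, 2, 0] = np.inf
        with pytest.raises(FloatingPointError, match="timestep"):
            ssm_scan_selective(x, params)

    def test_fused_backward_matches_finite_differences(self, rng):
        B, J, H, S = 2, 5, 3, 4
        params = SSMParams(H, S, rng)
        x = ad.Tensor(rng.normal(size=(B, J, H)), requires_grad=True)
        w = rng.normal(size=(B, J, H))
        (ssm_scan_selective(x, params) * ad.Tensor(w)).sum().backward()

        def value():
            return float((ssm_scan_selective(x, params).data * w).sum())

        for t in [x, *params.parameters()]:
            flat = t.data.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old, eps = flat[i], 1e-6
                flat[i] = old + eps
                fp = value()
                flat[i] = old - eps
                fm = value()
                flat[i] = old
                num = (fp - fm) / (2 * eps)
                ana = t.grad.ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana))


class TestDirectionPath:
    def _tied_paths(self, H=6, S=3, heads=2):
        fwd = DirectionPath(H, S, heads, "forward", np.random.default_rng(7))
        bwd = DirectionPath(H, S, heads, "backward", np.random.default_rng(7))
        return fwd, bwd

    def test_palindrome_with_tied_parameters(self, rng):
        """A palindromic sequence looks identical from both ends, so the
        backward path computes exactly the reversed forward output."""
        fwd, bwd = self._tied_paths()
        half = rng.normal(size=(1, 4, 6))
        x = np.concatenate([half, half[:, ::-1]], axis=1)  # palindromic sequence
        yf = fwd(ad.Tensor(x)).data
        yb = bwd(ad.Tensor(x)).data
        np.testing.assert_allclose(yb, yf[:, ::-1], atol=1e-10)

    def test_single_token_directions_coincide(self, rng):
        fwd, bwd = self._tied_paths()
        x = ad.Tensor(rng.normal(size=(2, 1, 6)))
        np.testing.assert_allclose(fwd(x).data, bwd(x).data, atol=1e-12)

    def test_backward_path_is_reversed_forward_with_tied_parameters(self, rng):
        fwd, bwd = self._tied_paths()
        x = rng.normal(size=(1, 5, 6))
        yb = bwd(ad.Tensor(x)).data
        yf_rev = fwd(ad.Tensor(x[:, ::-1].copy())).data[:, ::-1]
        np.testing.assert_allclose(yb, yf_rev, atol=1e-12)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            DirectionPath(4, 2, 2, "sideways", np.random.default_rng(0))


def _zero_parameters(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestEncoderBlock:
    CFG = EncoderConfig(model_width=7, hidden_width=8, state_size=3,
                        n_layers=2, n_heads=2)

    def test_zero_weights_reduce_to_identity(self, rng):
        block = EncoderBlock(self.CFG, rng)
        _zero_parameters(block)
        x = rng.normal(size=(2, 5, 7))
        np.testing.assert_array_equal(block(ad.Tensor(x)).data, x)

    def test_shape_preserved(self, rng):
        block = EncoderBlock(self.CFG, rng)
        assert block(ad.Tensor(rng.normal(size=(3, 6, 7)))).shape == (3, 6, 7)

    def test_matches_straight_line_reimplementation(self, rng):
        from scipy.special import expit

        block = EncoderBlock(self.CFG, rng)
        x = rng.normal(size=(2, 4, 7))
        # independent straight-line recomputation in plain numpy
        mu = x.mean(-1, keepdims=True)
        xc = x - mu
        u = xc / np.sqrt((xc**2).mean(-1, keepdims=True) + 1e-5)
        u = u * block.ln_gain.data + block.ln_bias.data
        xs = u @ block.Wx.data + block.bx.data
        zs = u @ block.Wz.data + block.bz.data

        def path(p, seq):
            mixed = p.mixer(ad.Tensor(seq)).data
            act = mixed * expit(mixed)
            return ssm_scan(act, *p.ssm.discretize(act))

        yf = path(block.fwd, xs)
        yb = path(block.bwd, xs[:, ::-1])[:, ::-1]
        g = zs * expit(zs)
        expected = (g * yf + g * yb) @ block.Wout.data + block.bout.data + x
        got = block(ad.Tensor(x)).data
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_conv1d_mixer_variant_runs(self, rng):
        cfg = EncoderConfig(model_width=5, hidden_width=6, state_size=2,
                            n_layers=1, n_heads=2, mixer="conv1d")
        block = EncoderBlock(cfg, rng)
        x = ad.Tensor(rng.normal(size=(2, 6, 5)), requires_grad=True)
        out = block(x)
        assert out.shape == (2, 6, 5)
        out.sum().backward()
        assert np.any(x.grad != 0)


class TestEncoderStack:
    def test_zero_layers_is_identity(self, rng):
        cfg = EncoderConfig(model_width=5, hidden_width=4, state_size=2,
                            n_layers=0, n_heads=2)
        enc = Encoder(cfg, rng)
        x = rng.normal(size=(1, 3, 5))
        np.testing.assert_array_equal(enc(ad.Tensor(x)).data, x)

    def test_two_layers_equal_manual_composition(self, rng):
        cfg = EncoderConfig(model_width=5, hidden_width=4, state_size=2,
                            n_layers=2, n_heads=2)
        enc = Encoder(cfg, rng)
        x = ad.Tensor(rng.normal(size=(1, 4, 5)))
        manual = enc.blocks[1](enc.blocks[0](x)).data
        np.testing.assert_array_equal(enc(x).data, manual)

    def test_gradient_flows_to_input(self, rng):
        cfg = EncoderConfig(model_width=5, hidden_width=4, state_size=2,
                            n_layers=1, n_heads=2)
        enc = Encoder(cfg, rng)
        x = ad.Tensor(rng.normal(size=(1, 3, 5)), requires_grad=True)
        enc(x).sum().backward()
        assert x.grad is not None and np.linalg.norm(x.grad) > 0

    def test_hidden_width_rounds_up_to_head_multiple(self):
        cfg = EncoderConfig(model_width=33, n_heads=4)
        assert cfg.hidden_width == 68 and cfg.hidden_width % 4 == 0
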