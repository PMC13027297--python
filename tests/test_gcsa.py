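"""GCSA: channel attention, channel shuffle, spatial attention.

The reference results are computed by an independent dense-algebra oracle
(explicit numpy loops over positions and kernel offsets), never by the
module's own ops.
"""

import numpy as np
import pytest

from aphidgrade.gcsa import (GCSA, ChannelAttention, GCSAConfig,
                             SpatialAttention, channel_shuffle,
                             shuffle_permutation)
from aphidgrade.nn import Tensor


def _zero_weights(module):
    for _, p in module.named_parameters():
        if p.data.ndim >= 1 and not np.all(p.data == 1.0):  # keep BN scales
            p.data[...] = 0.0
    # BN scale back to 1, shift 0 (identity on normalised input)
    for m in module.modules():
        if hasattr(m, "running_mean"):
            m.weight.data[...] = 1.0
            m.bias.data[...] = 0.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _oracle_channel_gate(x, fc1_w, fc1_b, fc2_w, fc2_b):
    """Per-position MLP gate computed position by position."""
    B, C, H, W = x.shape
    gate = np.zeros_like(x)
    for b in range(B):
        for i in range(H):
            for j in range(W):
                v = x[b, :, i, j]
                h = np.maximum(fc1_w @ v + fc1_b, 0.0)
                gate[b, :, i, j] = _sigmoid(fc2_w @ h + fc2_b)
    return gate


def _oracle_conv(x, w, b, pad):
    """Brute-force sliding-window cross-correlation with 'same' padding."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, O, H, W))
    for bb in range(B):
        for o in range(O):
            for i in range(H):
                for j in range(W):
                    out[bb, o, i, j] = (xp[bb, :, i:i + kh, j:j + kw]
                                        * w[o]).sum() + b[o]
    return out


class TestChannelShuffle:
    def test_documented_permutation_c8_g4(self):
        x = Tensor(np.arange(8, dtype=np.float32).reshape(8, 1, 1))
        out = channel_shuffle(x, 4)
        assert out.data[:, 0, 0].tolist() == [0, 2, 4, 6, 1, 3, 5, 7]

    def test_single_group_is_identity(self):
        x = Tensor(np.random.default_rng(0).normal(size=(2, 6, 3, 3)))
        assert np.array_equal(channel_shuffle(x, 1).data, x.data)

    @pytest.mark.parametrize("c,g", [(8, 4), (12, 3), (16, 2)])
    def test_shuffle_then_inverse_group_count_is_identity(self, c, g):
        x = Tensor(np.random.default_rng(1).normal(size=(1, c, 2, 2)))
        back = channel_shuffle(channel_shuffle(x, g), c // g)
        assert np.allclose(back.data, x.data)

    def test_is_a_pure_channel_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 12, 4, 4)).astype(np.float32)
        out = channel_shuffle(Tensor(x), 4).data
        perm = shuffle_permutation(12, 4)
        assert np.array_equal(out[0], x[0][perm])
        # value multiset per channel preserved exactly
        got = sorted(map(tuple, out[0].reshape(12, -1)))
        want = sorted(map(tuple, x[0].reshape(12, -1)))
        assert got == want

    def test_explicit_reshape_transpose_oracle(self):
        perm = shuffle_permutation(8, 4)
        oracle = np.arange(8).reshape(4, 2).T.reshape(-1)
        assert np.array_equal(perm, oracle)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError):
            channel_shuffle(Tensor(np.zeros((1, 7, 2, 2))), 4)


class TestChannelAttention:
    def test_zero_weights_give_half_gate(self):
        att = ChannelAttention(8, reduction=4, rng=np.random.default_rng(0))
        _zero_weights(att)
        x = Tensor(np.random.default_rng(3).normal(size=(2, 8, 3, 3)))
        out = att(x)
        assert np.allclose(out.data, 0.5 * x.data, atol=1e-6)

    def test_zero_input_is_absorbing(self):
        att = ChannelAttention(8, reduction=4, rng=np.random.default_rng(0))
        out = att(Tensor(np.zeros((1, 8, 2, 2))))
        assert np.all(out.data == 0.0)

    def test_hand_specified_mlp_matches_dense_oracle(self):
        att = ChannelAttention(4, reduction=4, rng=np.random.default_rng(0))
        att.fc1.weight.data[...] = [[0.5, -0.25, 0.1, 0.0]]
        att.fc1.bias.data[...] = [0.2]
        att.fc2.weight.data[...] = [[1.0], [-1.0], [0.5], [2.0]]
        att.fc2.bias.data[...] = [0.1, -0.1, 0.0, 0.3]
        x = np.array([1.0, 2.0, 3.0, 4.0], np.float32).reshape(1, 4, 1, 1)
        out = att(Tensor(x))
        gate = _oracle_channel_gate(x, att.fc1.weight.data, att.fc1.bias.data,
                                    att.fc2.weight.data, att.fc2.bias.data)
        assert np.allclose(out.data, gate * x, atol=1e-6)

    def test_unreducible_channel_count_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(3, reduction=4)


class TestSpatialAttention:
    def test_zero_weights_give_half_gate(self):
        att = SpatialAttention(8, reduction=4, kernel_size=3,
                               rng=np.random.default_rng(0))
        _zero_weights(att)
        att.eval()
        x = Tensor(np.random.default_rng(4).normal(size=(1, 8, 4, 4)))
        out = att(x)
        assert np.allclose(out.data, 0.5 * x.data, atol=1e-6)

    def test_bottleneck_conv_matches_brute_force_oracle(self):
        att = SpatialAttention(14, reduction=14, kernel_size=7,
                               rng=np.random.default_rng(5))
        att.eval()  # batch-norm at running stats (mean 0, var 1)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 14, 3, 3)).astype(np.float32)
        h = _oracle_conv(x, att.conv1.weight.data, att.conv1.bias.data, pad=3)
        h = h / np.sqrt(1.0 + 1e-5)  # eval BN, scale 1 shift 0
        h = np.maximum(h, 0.0)
        g = _oracle_conv(h, att.conv2.weight.data, att.conv2.bias.data, pad=3)
        g = _sigmoid(g / np.sqrt(1.0 + 1e-5))
        out = att(Tensor(x))
        assert np.allclose(out.data, g * x, atol=1e-4)

    def test_bottleneck_width_floors_at_one(self):
        att = SpatialAttention(10, reduction=14, kernel_size=3)
        assert att.conv1.weight.shape[0] == 1


class TestGCSAForward:
    def test_zero_input_residual_off(self):
        block = GCSA(8, GCSAConfig(groups=4, residual=False, kernel_size=3))
        block.eval()
        out = block(Tensor(np.zeros((1, 8, 3, 3))))
        assert np.all(out.data == 0.0)

    def test_zero_weight_residual_composition(self):
        """gates both 0.5 -> out = F + 0.25 * perm(F)."""
        block = GCSA(8, GCSAConfig(groups=4, residual=True, kernel_size=3))
        _zero_weights(block)
        block.eval()
        x = np.random.default_rng(7).normal(size=(1, 8, 3, 3)).astype(np.float32)
        out = block(Tensor(x))
        perm = shuffle_permutation(8, 4)
        assert np.allclose(out.data[0], x[0] + 0.25 * x[0][perm], atol=1e-6)

    @pytest.mark.parametrize("c,h,w", [(4, 2, 3), (8, 1, 1), (16, 4, 4)])
    def test_shape_preserved(self, c, h, w):
        block = GCSA(c, GCSAConfig(groups=4 if c % 4 == 0 else 1,
                                   kernel_size=3))
        out = block(Tensor(np.random.default_rng(8).normal(size=(2, c, h, w))))
        assert out.shape == (2, c, h, w)

    def test_unbatched_map_accepted(self):
        block = GCSA(8, GCSAConfig(kernel_size=3))
        out = block(Tensor(np.random.default_rng(9).normal(size=(8, 3, 3))))
        assert out.shape == (8, 3, 3)

    def test_gates_bounded_and_contractive_without_residual(self):
        rng = np.random.default_rng(10)
        block = GCSA(8, GCSAConfig(groups=2, residual=False, kernel_size=3))
        block.eval()
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        g_c = block.channel.gate(Tensor(x)).data
        assert np.all((g_c > 0) & (g_c < 1))
        out = block(Tensor(x))
        assert np.all(np.abs(out.data) <= np.abs(x)[:, shuffle_permutation(8, 2)]
                      + 1e-6)

    def test_dense_algebra_oracle_equivalence_random_maps(self):
        """Module output equals an explicit numpy re-evaluation for 100
        random (config, input) draws up to C=16, H=W=4."""
        rng = np.random.default_rng(11)
        for trial in range(100):
            c = int(rng.choice([4, 8, 12, 16]))
            h = int(rng.integers(1, 5))
            w = int(rng.integers(1, 5))
            g = int(rng.choice([gg for gg in (1, 2, 4) if c % gg == 0]))
            residual = bool(rng.integers(0, 2))
            block = GCSA(c, GCSAConfig(groups=g, residual=residual,
                                       kernel_size=3, seed=trial))
            block.eval()
            x = rng.normal(size=(1, c, h, w)).astype(np.float32)
            gate_c = _oracle_channel_gate(
                x, block.channel.fc1.weight.data, block.channel.fc1.bias.data,
                block.channel.fc2.weight.data, block.channel.fc2.bias.data)
            mid = (gate_c * x)[:, shuffle_permutation(c, g)]
            hmid = _oracle_conv(mid, block.spatial.conv1.weight.data,
                                block.spatial.conv1.bias.data, pad=1)
            hmid = np.maximum(hmid / np.sqrt(1.0 + 1e-5), 0.0)
            gsp = _oracle_conv(hmid, block.spatial.conv2.weight.data,
                               block.spatial.conv2.bias.data, pad=1)
            gsp = _sigmoid(gsp / np.sqrt(1.0 + 1e-5))
            expect = gsp * mid + (x if residual else 0.0)
            out = block(Tensor(x))
            assert np.allclose(out.data, expect, atol=5e-4), f"trial {trial}"

    def test_groups_must_divide_channels(self):
        with pytest.raises(ValueError):
            GCSA(6, GCSAConfig(groups=4))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            GCSAConfig(kernel_size=4)
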