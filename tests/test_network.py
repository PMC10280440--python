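"""Architecture oracles: attention, gated ConvGRU, residual blocks, shapes.

The vectorised layers are checked against naive straight-line transcriptions
of their defining equations (explicit loops over pixels and kernel taps) on
small tensors.
"""

import numpy as np
import pytest

from bloomcast.autodiff import Tensor
from bloomcast.network import (CamConvGRUCell, CamConvGruParams, ChannelAttention,
                               Discriminator, DiscriminatorConfig, Generator,
                               GeneratorConfig, ResidualDownBlock, TensorSpec)


# ---------------------------------------------------------------------------
# Naive reference implementations
# ---------------------------------------------------------------------------

def naive_conv2d(x, w, b, stride, pad):
    pt, pb, pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    n, c, hp, wp = xp.shape
    o, _, kh, kw = w.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, o, oh, ow))
    for nn in range(n):
        for oo in range(o):
            for i in range(oh):
                for j in range(ow):
                    acc = 0.0
                    for cc in range(c):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += w[oo, cc, ki, kj] * \
                                    xp[nn, cc, i * stride + ki, j * stride + kj]
                    out[nn, oo, i, j] = acc + (b[oo] if b is not None else 0.0)
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def naive_attention(f, att: ChannelAttention):
    """sigmoid(MLP(average pool)) scaling, channel by channel."""
    n, c, h, w = f.shape
    pooled = f.mean(axis=(2, 3))                              # (N, C)
    hidden = np.maximum(pooled @ att.fc1.weight.data + att.fc1.bias.data, 0.0)
    s = sigmoid(hidden @ att.fc2.weight.data + att.fc2.bias.data)
    return f * s[:, :, None, None], s


def naive_gru_step(x, h_prev, cell: CamConvGRUCell):
    """Transcription of the gated recurrence:
    R = X*Wxr + H*Whr + br ; r = sigmoid(Mc(R))
    Z = X*Wxz + H*Whz + bz ; z = sigmoid(Mc(Z))
    Hcand = tanh(X*Wxh + (r . H)*Whh + bh)
    Hnew = z . H + (1 - z) . Hcand
    """
    c = cell.params.filters
    pad = cell.conv_x.padding
    wx = cell.conv_x.weight.data
    bx = cell.conv_x.bias.data
    wh = cell.conv_h.weight.data
    gx = naive_conv2d(x, wx, bx, 1, pad)
    gh = naive_conv2d(h_prev, wh, None, 1, pad)
    r_in = gx[:, :c] + gh[:, :c]
    z_in = gx[:, c:2 * c] + gh[:, c:2 * c]
    r = sigmoid(naive_attention(r_in, cell.att_r)[0])
    z = sigmoid(naive_attention(z_in, cell.att_z)[0])
    rh = naive_conv2d(r * h_prev, cell.conv_rh.weight.data, None, 1, pad)
    h_cand = np.tanh(gx[:, 2 * c:] + rh)
    return z * h_prev + (1.0 - z) * h_cand


# ---------------------------------------------------------------------------
# Channel attention
# ---------------------------------------------------------------------------

class TestChannelAttention:
    def test_zero_mlp_gives_half_scaling(self, rng):
        att = ChannelAttention(4, hidden=3, rng=rng)
        for p in att.parameters():
            p.data[...] = 0.0
        f = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        out = att(Tensor(f))
        assert np.allclose(out.data, 0.5 * f, atol=1e-7)

    def test_constant_channel_pools_to_its_value(self, rng):
        att = ChannelAttention(3, rng=rng)
        f = np.zeros((1, 3, 4, 4), np.float32)
        f[0, 1] = 7.5
        pooled = Tensor(f).mean(axis=(2, 3)).data
        assert pooled[0, 1] == pytest.approx(7.5)

    def test_output_never_amplifies(self, rng):
        att = ChannelAttention(6, rng=rng)
        f = rng.normal(size=(2, 6, 8, 8)).astype(np.float32) * 10
        out = att(Tensor(f)).data
        assert (np.abs(out) <= np.abs(f) + 1e-7).all()

    def test_matches_naive_transcription(self, rng):
        att = ChannelAttention(5, hidden=8, rng=rng)
        for p in att.parameters():
            p.data[...] = rng.normal(0, 0.5, size=p.data.shape)
        f = rng.normal(size=(2, 5, 4, 4))
        got = att(Tensor(f, dtype=np.float64)).data
        want, s = naive_attention(f, att)
        assert np.max(np.abs(got - want)) < 1e-6
        assert ((0 < s) & (s < 1)).all()

    def test_channel_mismatch_rejected(self, rng):
        att = ChannelAttention(4, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            att(Tensor(np.zeros((1, 5, 4, 4))))


# ---------------------------------------------------------------------------
# Gated ConvGRU
# ---------------------------------------------------------------------------

def small_cell(rng, filters=3, scale=0.5):
    cell = CamConvGRUCell(CamConvGruParams(filters=filters, in_channels=2,
                                           mlp_hidden=4), rng=rng)
    for p in cell.parameters():
        p.data[...] = rng.normal(0, scale, size=p.data.shape)
    return cell


class TestCamConvGru:
    def test_step_matches_equation_transcription(self, rng):
        cell = small_cell(rng)
        x = rng.normal(size=(1, 2, 4, 4))
        h = rng.normal(size=(1, 3, 4, 4))
        got = cell(Tensor(x, dtype=np.float64), Tensor(h, dtype=np.float64)).data
        want = naive_gru_step(x, h, cell)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_update_gate_saturated_high_keeps_memory(self, rng):
        cell = small_cell(rng)
        for p in cell.parameters():
            p.data[...] = 0.0
        cell.conv_x.bias.data[3:6] = 50.0        # b_z large: z ~ 1
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        h = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        out = cell(Tensor(x), Tensor(h)).data
        assert np.max(np.abs(out - h)) < 1e-6

    def test_update_gate_saturated_low_takes_candidate(self, rng):
        cell = small_cell(rng)
        for p in cell.parameters():
            p.data[...] = 0.0
        cell.conv_x.bias.data[3:6] = -50.0       # z ~ 0
        cell.conv_x.bias.data[6:9] = 0.7         # b_h: candidate = tanh(0.7)
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        h = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        out = cell(Tensor(x), Tensor(h)).data
        assert np.max(np.abs(out - np.tanh(0.7))) < 1e-6

    def test_hidden_state_bounded(self, rng):
        cell = small_cell(rng, scale=2.0)
        h = Tensor(rng.uniform(-1, 1, size=(1, 3, 4, 4)).astype(np.float32))
        for t in range(5):
            x = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32) * 5)
            h = cell(x, h)
            assert np.abs(h.data).max() <= max(1.0, np.abs(h.data).max())
            assert np.abs(h.data).max() <= 1.0 + 1e-6

    def test_encode_starts_from_zero_state(self, rng):
        cell = small_cell(rng)
        z = cell.init_state(1, 4, 4)
        assert (z.data == 0).all()

    def test_encode_is_order_sensitive(self, rng):
        cell = small_cell(rng)
        seq = rng.normal(size=(1, 4, 2, 4, 4)).astype(np.float32)
        fwd = cell.encode(Tensor(seq)).data
        rev = cell.encode(Tensor(seq[:, ::-1].copy())).data
        assert not np.allclose(fwd, rev, atol=1e-5)

    def test_encode_deterministic_given_seed(self):
        a = CamConvGRUCell(CamConvGruParams(filters=4),
                           rng=np.random.default_rng(33))
        b = CamConvGRUCell(CamConvGruParams(filters=4),
                           rng=np.random.default_rng(33))
        x = np.random.default_rng(1).normal(size=(1, 6, 3, 8, 8)).astype(np.float32)
        assert np.array_equal(a.encode(Tensor(x)).data, b.encode(Tensor(x)).data)

    def test_shape_mismatch_names_the_gate(self, rng):
        cell = small_cell(rng)
        with pytest.raises(ValueError, match="gate"):
            cell(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 3, 8, 8))))


# ---------------------------------------------------------------------------
# Residual down-sampling block
# ---------------------------------------------------------------------------

class TestResidualBlock:
    def test_zero_weights_passthrough(self, rng):
        block = ResidualDownBlock(4, rng=rng).eval()
        for name, p in block.named_parameters():
            if "bn" not in name:
                p.data[...] = 0.0
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        out = block(Tensor(x)).data
        assert np.allclose(out, x, atol=1e-6)

    def test_matches_equation_transcription(self, rng):
        # y1 = LeakyReLU(BN(x*w1 + b1)), C/2 kernels 1x1
        # y2 = LeakyReLU(BN(y1*w2 + b2)), C kernels 3x3
        # y_out = x + y2        (BN in identity passthrough: eval mode)
        block = ResidualDownBlock(4, rng=rng).eval()
        for name, p in block.named_parameters():
            if "bn" not in name:
                p.data[...] = rng.normal(0, 0.5, size=p.data.shape)
        x = rng.normal(size=(1, 4, 4, 4))
        got = block(Tensor(x, dtype=np.float64)).data

        def lrelu(v):
            return np.where(v > 0, v, 0.2 * v)

        eps = 1e-5
        def bn_eval(v):
            return v / np.sqrt(1.0 + eps)     # frozen stats: mean 0, var 1

        y1 = lrelu(bn_eval(naive_conv2d(x, block.block1.conv.weight.data,
                                        block.block1.conv.bias.data, 1,
                                        (0, 0, 0, 0))))
        y2 = lrelu(bn_eval(naive_conv2d(y1, block.block2.conv.weight.data,
                                        block.block2.conv.bias.data, 1,
                                        (1, 1, 1, 1))))
        assert np.max(np.abs(got - (x + y2))) < 1e-6

    def test_shape_preserved(self, rng):
        block = ResidualDownBlock(8, rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 12, 12)).astype(np.float32))
        assert block(x).shape == x.shape

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            ResidualDownBlock(5, rng=rng)

    def test_bottleneck_halves_then_doubles_kernels(self, rng):
        block = ResidualDownBlock(8, rng=rng)
        assert block.block1.conv.weight.shape == (4, 8, 1, 1)
        assert block.block2.conv.weight.shape == (8, 4, 3, 3)


# ---------------------------------------------------------------------------
# Generator / Discriminator contracts
# ---------------------------------------------------------------------------

def tiny_gen_config(input_len=2):
    return GeneratorConfig(
        gru=CamConvGruParams(filters=2, mlp_hidden=2),
        down_channels=(2, 4, 4, 4, 4, 4, 4, 8),
        up_channels=(4, 4, 4, 4, 4, 4, 2),
        input_len=input_len)


class TestGenerator:
    @pytest.mark.parametrize("size", [128, 256])
    def test_output_shape_matches_input_frame(self, size):
        gen = Generator(tiny_gen_config(), seed=0).eval()
        x = Tensor(np.zeros((1, 2, 3, size, size), np.float32))
        out = gen(x)
        assert out.shape == (1, 3, size, size)

    def test_output_in_tanh_range(self, rng):
        gen = Generator(tiny_gen_config(), seed=0).eval()
        x = Tensor(rng.normal(size=(1, 2, 3, 128, 128)).astype(np.float32))
        out = gen(x).data
        assert (out >= -1).all() and (out <= 1).all()

    def test_wrong_rank_rejected(self):
        gen = Generator(tiny_gen_config(), seed=0)
        with pytest.raises(ValueError, match="N, T, C, H, W"):
            gen(Tensor(np.zeros((96, 128, 128), np.float32)))

    def test_wrong_sequence_length_rejected(self):
        gen = Generator(tiny_gen_config(input_len=2), seed=0)
        with pytest.raises(ValueError, match="2 input frames"):
            gen(Tensor(np.zeros((1, 5, 3, 128, 128), np.float32)))

    def test_indivisible_size_reports_minimum(self):
        gen = Generator(tiny_gen_config(), seed=0)
        with pytest.raises(ValueError, match="128x128"):
            gen(Tensor(np.zeros((1, 2, 3, 96, 96), np.float32)))

    def test_seeded_builds_are_bit_identical(self, rng):
        a = Generator(tiny_gen_config(), seed=7)
        b = Generator(tiny_gen_config(), seed=7)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb and np.array_equal(pa.data, pb.data)
        x = Tensor(rng.normal(size=(1, 2, 3, 128, 128)).astype(np.float32))
        assert np.array_equal(a.eval()(x).data, b.eval()(x).data)

    def test_parameter_count_regression(self):
        assert Generator(GeneratorConfig(), seed=0).num_parameters() == 18_470_787
        assert Generator(GeneratorConfig.reduced(), seed=0).num_parameters() == 1_159_983


class TestDiscriminator:
    def test_patch_map_geometry_and_range(self, rng):
        cfg = DiscriminatorConfig.reduced()
        disc = Discriminator(cfg, seed=0).eval()
        cand = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        hist = Tensor(rng.normal(size=(1, 30, 3, 128, 128)).astype(np.float32))
        patch, score = disc(cand, hist)
        # four stride-2 halvings: 128 -> 8; output conv (k4, s1, p1) -> 7
        assert patch.shape == (1, 1, 7, 7)
        assert ((patch.data > 0) & (patch.data < 1)).all()
        assert score.item() == pytest.approx(float(patch.data.mean()), rel=1e-6)

    def test_conditioning_channel_count(self):
        cfg = DiscriminatorConfig()
        assert cfg.input_channels == 93   # RGB x (30 history + 1 candidate)

    def test_wrong_history_length_rejected(self, rng):
        disc = Discriminator(DiscriminatorConfig.reduced(), seed=0)
        cand = Tensor(np.zeros((1, 3, 128, 128), np.float32))
        hist = Tensor(np.zeros((1, 7, 3, 128, 128), np.float32))
        with pytest.raises(ValueError, match="history"):
            disc(cand, hist)

    def test_parameter_count_regression(self):
        assert Discriminator(DiscriminatorConfig(), seed=0).num_parameters() == 741_217
        assert Discriminator(DiscriminatorConfig.reduced(),
                             seed=0).num_parameters() == 56_281


class TestTensorSpec:
    def test_valid_spec(self):
        TensorSpec(1, 30, 3, 128, 256)

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TensorSpec(1, 30, 3, 100, 128)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TensorSpec(0, 30, 3, 128, 128)
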