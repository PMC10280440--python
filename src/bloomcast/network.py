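"""Architecture of the forecasting GAN.

The generator couples a temporal encoder with a spatial U-net:

* **Channel attention** (squeeze-and-excitation style): per-channel weights
  s = sigmoid(MLP(global average pool)) rescale the feature map, M_c(F) = s∘F.
* **Attention-gated ConvGRU**: a convolutional GRU whose reset and update
  gates pass through channel attention before their sigmoid,
  r_t = σ[M_c(X_t∗W_xr + H_{t−1}∗W_hr + b_r)] (update gate analogous), with
  candidate state H̃_t = tanh(X_t∗W_xh + (r_t∘H_{t−1})∗W_hh + b_h) and
  H_t = z_t∘H_{t−1} + (1−z_t)∘H̃_t.  Thirty daily frames are folded into
  one hidden feature map.
* **Residual U-net**: a stride-1 stem plus seven stride-2 down-sampling
  layers (each conv+BN+LeakyReLU followed by a residual bottleneck:
  1×1 conv to C/2, 3×3 conv back to C, skip-added), mirrored by seven
  up-sampling layers (4×4 stride-2 transposed conv + BN + LeakyReLU +
  dropout + stride-1 conv block) with U-net skip concatenation, and a 4×4
  stride-1 output convolution with tanh.

The discriminator is a PatchGAN conditioned on the 30 historical frames
stacked along the channel axis next to the candidate frame (93 channels for
RGB), scoring overlapping patches through four stride-2 convolutions and
averaging the patch probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Linear, Module

__all__ = [
    "TensorSpec", "CamConvGruParams", "GeneratorConfig", "DiscriminatorConfig",
    "ChannelAttention", "CamConvGRUCell", "ResidualDownBlock",
    "Generator", "Discriminator",
]

#: Number of stride-2 halvings in the U-net; input sides must divide 2**7.
N_HALVINGS = 7


@dataclass(frozen=True)
class TensorSpec:
    """Shape contract for a batched frame-sequence tensor."""
    batch: int
    time: int
    channels: int
    height: int
    width: int

    def __post_init__(self):
        for name in ("batch", "time", "channels", "height", "width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        validate_spatial(self.height, self.width)


def validate_spatial(h: int, w: int) -> None:
    m = 2 ** N_HALVINGS
    if h % m or w % m:
        raise ValueError(
            f"spatial size {h}x{w} must be divisible by {m} "
            f"(minimal legal size {m}x{m})")


@dataclass(frozen=True)
class CamConvGruParams:
    """Temporal-encoder hyperparameters (defaults: 32 filters, 4x4 kernels,
    attention MLP 8 hidden units)."""
    filters: int = 32
    kernel_size: int = 4
    mlp_hidden: int = 8
    in_channels: int = 3
    share_attention: bool = False


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator hyperparameters; defaults follow the reference architecture
    (down channels 32..512, up channels 256..32)."""
    gru: CamConvGruParams = CamConvGruParams()
    down_channels: tuple = (32, 64, 128, 256, 256, 256, 256, 512)
    up_channels: tuple = (256, 256, 256, 256, 128, 64, 32)
    output_channels: int = 3
    down_kernel: int = 3
    up_kernel: int = 4
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5
    input_len: int = 30

    def __post_init__(self):
        if len(self.up_channels) != N_HALVINGS:
            raise ValueError(f"need exactly {N_HALVINGS} up-sampling layers")
        if len(self.down_channels) != N_HALVINGS + 1:
            raise ValueError(f"need a stem plus {N_HALVINGS} down-sampling layers")
        for c in self.down_channels:
            if c % 2:
                raise ValueError("residual bottleneck requires even channels")

    @classmethod
    def reduced(cls, factor: int = 4, filters: int = 8) -> "GeneratorConfig":
        """Scaled-down variant (channels / factor) for CPU-scale experiments."""
        return cls(
            gru=CamConvGruParams(filters=filters),
            down_channels=tuple(c // factor for c in cls.down_channels),
            up_channels=tuple(c // factor for c in cls.up_channels),
        )


@dataclass(frozen=True)
class DiscriminatorConfig:
    """PatchGAN hyperparameters (defaults: channels 32..256, 4x4 kernels,
    30 channel-stacked historical frames as conditioning labels)."""
    conv_channels: tuple = (32, 64, 128, 256)
    kernel: int = 4
    label_frames: int = 30
    in_channels: int = 3
    leaky_slope: float = 0.2
    first_bn: bool = False

    @property
    def input_channels(self) -> int:
        return self.in_channels * (self.label_frames + 1)

    @classmethod
    def reduced(cls, factor: int = 4) -> "DiscriminatorConfig":
        return cls(conv_channels=tuple(c // factor for c in cls.conv_channels))


def _same_pad(kernel: int) -> tuple:
    """Asymmetric zero padding that preserves H and W at stride 1."""
    total = kernel - 1
    before = total // 2
    return (before, total - before, before, total - before)


class ChannelAttention(Module):
    """M_c(F) = sigmoid(MLP(AvgPool(F))) ∘ F with an MLP of C → hidden → C."""

    def __init__(self, channels: int, hidden: int = 8, rng=None):
        super().__init__()
        self.channels = channels
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def weights(self, f: Tensor) -> Tensor:
        """Per-channel attention weights s, shape (N, C), each in (0, 1)."""
        if f.shape[1] != self.channels:
            raise ValueError(
                f"channel attention built for {self.channels} channels, got {f.shape[1]}")
        pooled = f.mean(axis=(2, 3))                 # (N, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, f: Tensor) -> Tensor:
        s = self.weights(f)
        return f * s.reshape(s.shape[0], s.shape[1], 1, 1)


class CamConvGRUCell(Module):
    """Convolutional GRU step with channel attention ahead of each gate."""

    def __init__(self, params: CamConvGruParams = CamConvGruParams(), rng=None):
        super().__init__()
        self.params = params
        c, k = params.filters, params.kernel_size
        pad = _same_pad(k)
        # gate biases b_r, b_z, b_h live on the input convolutions
        self.conv_x = Conv2d(params.in_channels, 3 * c, k, 1, pad, bias=True, rng=rng)
        self.conv_h = Conv2d(c, 2 * c, k, 1, pad, bias=False, rng=rng)
        self.conv_rh = Conv2d(c, c, k, 1, pad, bias=False, rng=rng)
        self.att_r = ChannelAttention(c, params.mlp_hidden, rng=rng)
        self.att_z = (self.att_r if params.share_attention
                      else ChannelAttention(c, params.mlp_hidden, rng=rng))

    def init_state(self, batch: int, h: int, w: int) -> Tensor:
        return Tensor(np.zeros((batch, self.params.filters, h, w), np.float32))

    def forward(self, x: Tensor, h_prev: Tensor) -> Tensor:
        c = self.params.filters
        if h_prev.shape[1] != c:
            raise ValueError(f"hidden state has {h_prev.shape[1]} channels, "
                             f"gates expect {c}")
        if x.shape[2:] != h_prev.shape[2:]:
            raise ValueError(
                f"reset gate: input spatial {x.shape[2:]} != hidden {h_prev.shape[2:]}")
        gx = self.conv_x(x)                          # [r | z | h] stacks
        gh = self.conv_h(h_prev)                     # [r | z]
        r_in = gx.narrow(1, 0, c) + gh.narrow(1, 0, c)
        z_in = gx.narrow(1, c, c) + gh.narrow(1, c, c)
        r = self.att_r(r_in).sigmoid()
        z = self.att_z(z_in).sigmoid()
        h_cand = (gx.narrow(1, 2 * c, c) + self.conv_rh(r * h_prev)).tanh()
        return z * h_prev + (1.0 - z) * h_cand

    def encode(self, frames: Tensor) -> Tensor:
        """Fold a (N, T, C, H, W) sequence into the final hidden state H_T."""
        n, t, c, h, w = frames.shape
        state = self.init_state(n, h, w)
        for i in range(t):
            x = frames.narrow(1, i, 1).reshape(n, c, h, w)
            state = self.forward(x, state)
        return state


class ConvBlock(Module):
    """conv2d module: convolution + batch norm + LeakyReLU."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 slope: float = 0.2, rng=None, bn: bool = True):
        super().__init__()
        pad = _same_pad(kernel) if stride == 1 else (1, 1, 1, 1)
        self.conv = Conv2d(cin, cout, kernel, stride, pad, rng=rng)
        self.bn = BatchNorm2d(cout) if bn else None
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return y.leaky_relu(self.slope)


class ResidualDownBlock(Module):
    """Residual bottleneck: 1×1 conv to C/2, 3×3 conv back to C, skip-added.

    The second convolution has twice the kernels of the first; both are
    stride 1 and shape-preserving, so the output shape equals the input.
    """

    def __init__(self, channels: int, slope: float = 0.2, rng=None):
        super().__init__()
        if channels % 2:
            raise ValueError("residual bottleneck requires even channels")
        self.block1 = ConvBlock(channels, channels // 2, 1, 1, slope, rng=rng)
        self.block2 = ConvBlock(channels // 2, channels, 3, 1, slope, rng=rng)

    def forward(self, x_out: Tensor) -> Tensor:
        y1 = self.block1(x_out)
        y2 = self.block2(y1)
        return x_out + y2


class DownLayer(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 slope: float, rng=None):
        super().__init__()
        self.conv = ConvBlock(cin, cout, kernel, stride, slope, rng=rng)
        self.res = ResidualDownBlock(cout, slope, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.res(self.conv(x))


class UpLayer(Module):
    """Transposed conv + BN + LeakyReLU + dropout + stride-1 conv block."""

    def __init__(self, cin: int, cout: int, kernel: int, slope: float,
                 dropout: float, rng=None, drop_rng=None):
        super().__init__()
        self.deconv = ConvTranspose2d(cin, cout, kernel, 2, 1, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.dropout = Dropout(dropout, rng=drop_rng)
        self.conv = ConvBlock(cout, cout, 3, 1, slope, rng=rng)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.deconv(x)).leaky_relu(self.slope)
        return self.conv(self.dropout(y))


class Generator(Module):
    """Temporal encoder + residual U-net mapping 30 frames to the next frame.

    Input: (N, 30, 3, H, W) normalised to [−1, 1]; output (N, 3, H, W) in
    [−1, 1] (tanh).  H and W must divide 2**7.
    """

    def __init__(self, config: GeneratorConfig = GeneratorConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.cell = CamConvGRUCell(config.gru, rng=rng)
        down = config.down_channels
        up = config.up_channels
        slope = config.leaky_slope
        self.downs = []
        cin = config.gru.filters
        for i, cout in enumerate(down):
            layer = DownLayer(cin, cout, config.down_kernel, 1 if i == 0 else 2,
                              slope, rng=rng)
            setattr(self, f"down{i}", layer)
            self.downs.append(layer)
            cin = cout
        self.ups = []
        cin = down[-1]
        for i, cout in enumerate(up):
            layer = UpLayer(cin, cout, config.up_kernel, slope,
                            config.dropout_rate, rng=rng, drop_rng=drop_rng)
            setattr(self, f"up{i}", layer)
            self.ups.append(layer)
            # next input: this output concatenated with the mirror skip
            cin = cout + down[N_HALVINGS - 1 - i]
        self.out_conv = Conv2d(cin, config.output_channels, 4, 1, _same_pad(4), rng=rng)

    def encode_sequence(self, frames: Tensor) -> Tensor:
        if frames.ndim != 5:
            raise ValueError(f"expected (N, T, C, H, W) input, got shape {frames.shape}")
        n, t, c, h, w = frames.shape
        if t != self.config.input_len:
            raise ValueError(f"expected {self.config.input_len} input frames, got {t}")
        validate_spatial(h, w)
        return self.cell.encode(frames)

    def forward(self, frames: Tensor) -> Tensor:
        feat = self.encode_sequence(frames).leaky_relu(self.config.leaky_slope)
        skips = []
        x = feat
        for layer in self.downs:
            x = layer(x)
            skips.append(x)
        for i, layer in enumerate(self.ups):
            x = layer(x)
            x = concat([x, skips[N_HALVINGS - 1 - i]], axis=1)
        return self.out_conv(x).tanh()


class Discriminator(Module):
    """PatchGAN over the candidate frame stacked with 30 history frames."""

    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig(),
                 seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        cin = config.input_channels
        self.blocks = []
        for i, cout in enumerate(config.conv_channels):
            block = ConvBlock(cin, cout, config.kernel, 2, config.leaky_slope,
                              rng=rng, bn=config.first_bn if i == 0 else True)
            setattr(self, f"block{i}", block)
            self.blocks.append(block)
            cin = cout
        self.out_conv = Conv2d(cin, 1, config.kernel, 1, (1, 1, 1, 1), rng=rng)

    def forward(self, candidate: Tensor, history: Tensor):
        """Return (patch probability map, scalar mean score)."""
        if history.ndim == 5:
            n, t, c, h, w = history.shape
            if t != self.config.label_frames:
                raise ValueError(
                    f"expected {self.config.label_frames} history frames, got {t}")
            history = history.reshape(n, t * c, h, w)
        elif history.shape[1] != self.config.label_frames * self.config.in_channels:
            raise ValueError(
                f"expected {self.config.label_frames} stacked history frames, got "
                f"{history.shape[1] // self.config.in_channels}")
        if candidate.shape[2:] != history.shape[2:]:
            raise ValueError("candidate and history must share spatial shape")
        x = concat([candidate, history], axis=1)
        for block in self.blocks:
            x = block(x)
        patch = self.out_conv(x).sigmoid()
        return patch, patch.mean()
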