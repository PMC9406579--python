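"""The residual-dense-attention (RDA) U-Net layer graph.

The network is a U-shaped encoder/decoder for single-channel CT slices.
Each encoder stage composes a residual block (H(x) = F(x) + x, two 3x3
conv/norm/ReLU stages with an identity or 1x1 shortcut) with a dense block
(each layer consumes the concatenation of the block input and all previous
layer outputs, adding ``growth_rate`` channels per layer), followed by 2x2
max pooling.  The decoder upsamples with kernel-2/stride-2 transposed
convolutions; at every resolution an additive attention gate computes
per-pixel coefficients alpha in (0,1) from the coarser decoder feature
(the gating signal g) and the encoder skip feature x, and the gated skip
x * alpha is concatenated with the upsampled path before two 3x3
convolutions.  A 1x1 convolution plus sigmoid produces the probability map
at input resolution.

Channel widths, block depths and growth rates are free hyperparameters of
the published design; :class:`ArchitectureConfig` makes them explicit and
configurable, with defaults chosen to land in the ~10M-parameter range of
the original model.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Literal

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor

__all__ = [
    "ArchitectureConfig",
    "ResBlock",
    "DenseBlock",
    "AttentionGate",
    "RDAUNet",
    "build_res_block",
    "build_dense_block",
    "build_attention_gate",
    "build_rda_unet",
    "count_parameters",
    "forward",
    "describe",
]


# --------------------------------------------------------------------- config
@dataclasses.dataclass
class ArchitectureConfig:
    """Hyperparameters of the RDA U-Net.

    Parameters
    ----------
    input_size
        Side length of the (square) network input, px.  Must be divisible by
        ``2**depth`` so pooling and up-convolution round-trip exactly.
    input_channels
        Channels of the input image (1 for CT).
    depth
        Number of encoder resolution levels (a bottleneck sits below them).
    base_filters
        Channel width of the top encoder level; widths double per level.
    dense_layers
        Convolutions per dense block.
    growth_rate
        Channels added by each dense layer; ``None`` means half the stage
        width at that level.
    attention_inter_channels
        Width of the attention gate's intermediate space; ``None`` means
        half the skip's channels.
    output_channels
        Channels of the probability map (1 for binary segmentation).
    block_mode
        ``serial`` composes residual then dense block per stage;
        ``res_only``/``dense_only`` ablate one of the two.
    norm
        ``batchnorm`` or ``none``.
    """

    input_size: int = 224
    input_channels: int = 1
    depth: int = 4
    base_filters: int = 16
    dense_layers: int = 4
    growth_rate: int | None = None
    attention_inter_channels: int | None = None
    output_channels: int = 1
    block_mode: Literal["serial", "res_only", "dense_only"] = "serial"
    norm: Literal["batchnorm", "none"] = "batchnorm"

    def validate(self) -> None:
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        for field in ("input_size", "input_channels", "base_filters", "output_channels"):
            if getattr(self, field) < 1:
                raise ConfigurationError(f"{field} must be >= 1, got {getattr(self, field)}")
        if self.dense_layers < 0:
            raise ConfigurationError(f"dense_layers must be >= 0, got {self.dense_layers}")
        if self.growth_rate is not None and self.growth_rate < 1:
            raise ConfigurationError(f"growth_rate must be >= 1, got {self.growth_rate}")
        if self.input_size % (2**self.depth) != 0:
            raise ConfigurationError(
                f"input_size={self.input_size} not divisible by 2**depth={2**self.depth}"
            )
        if self.block_mode not in ("serial", "res_only", "dense_only"):
            raise ConfigurationError(f"block_mode: unknown mode {self.block_mode!r}")
        if self.norm not in ("batchnorm", "none"):
            raise ConfigurationError(f"norm: unknown mode {self.norm!r}")

    def stage_width(self, level: int) -> int:
        return self.base_filters * 2**level

    def stage_growth(self, level: int) -> int:
        return self.growth_rate if self.growth_rate is not None else max(1, self.stage_width(level) // 2)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _norm_layer(channels: int, norm: str) -> nn.Module:
    return nn.BatchNorm2d(channels) if norm == "batchnorm" else nn.Identity()


# --------------------------------------------------------------------- blocks
class ResBlock(nn.Module):
    """H(x) = F(x) + shortcut(x).

    F is two 3x3 conv -> norm -> ReLU stages; the shortcut is the identity
    when channel counts match and a 1x1 convolution otherwise.  With the
    residual branch zeroed the block is exactly the identity map, which the
    tests assert numerically.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        norm: str = "batchnorm",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ConfigurationError("res block channel counts must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.norm1 = _norm_layer(out_channels, norm)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.norm2 = _norm_layer(out_channels, norm)
        self.shortcut = (
            nn.Identity()
            if in_channels == out_channels
            else nn.Conv2d(in_channels, out_channels, 1, rng=rng)
        )
        self.act = nn.ReLU()

    def forward(self, x: Tensor) -> Tensor:
        r = self.act(self.norm1(self.conv1(x)))
        r = self.norm2(self.conv2(r))
        return self.shortcut(x) + r

    def zero_residual_branch(self) -> None:
        """Zero F's parameters so the block reduces to its shortcut."""
        for layer in (self.conv1, self.conv2):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        for norm in (self.norm1, self.norm2):
            if isinstance(norm, nn.BatchNorm2d):
                norm.beta.data[:] = 0.0
                norm._buffers["running_mean"][:] = 0.0


class DenseBlock(nn.Module):
    """Densely connected 3x3 convolutions with feature reuse.

    Layer i consumes the concatenation of the block input and every earlier
    layer's output and emits ``growth_rate`` channels; the block output is
    the final concatenation, ``in_channels + layers * growth_rate`` wide.
    """

    def __init__(
        self,
        in_channels: int,
        layers: int,
        growth_rate: int,
        norm: str = "batchnorm",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if layers < 0:
            raise ConfigurationError("dense block layers must be >= 0")
        if layers > 0 and growth_rate < 1:
            raise ConfigurationError("dense block growth_rate must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.growth_rate = growth_rate
        self.out_channels = in_channels + layers * growth_rate
        self.convs: list[nn.Module] = []
        self.norms: list[nn.Module] = []
        width = in_channels
        for _ in range(layers):
            self.convs.append(nn.Conv2d(width, growth_rate, 3, padding=1, rng=rng))
            self.norms.append(_norm_layer(growth_rate, norm))
            width += growth_rate
        self.act = nn.ReLU()

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        for conv, norm in zip(self.convs, self.norms):
            inp = features[0] if len(features) == 1 else nn.concatenate(features, axis=1)
            features.append(self.act(norm(conv(inp))))
        return features[0] if len(features) == 1 else nn.concatenate(features, axis=1)


class AttentionGate(nn.Module):
    """Additive soft-attention gate on a skip connection.

    The gating signal ``g`` comes from one level below the skip feature
    ``x`` (half its spatial size).  ``x`` is brought to g's grid by a
    learned stride-2 1x1 convolution; the two are projected into an
    intermediate space, summed, passed through ReLU, reduced to one channel
    (psi) and squashed by a sigmoid into coefficients alpha in (0,1), which
    are upsampled back to x's grid and multiplied into x.
    """

    def __init__(
        self,
        skip_channels: int,
        gate_channels: int,
        inter_channels: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if skip_channels < 1 or gate_channels < 1:
            raise ConfigurationError("attention gate channel counts must be >= 1")
        inter = inter_channels if inter_channels is not None else max(1, skip_channels // 2)
        if inter < 1:
            raise ConfigurationError("attention_inter_channels must be >= 1")
        rng = rng or np.random.default_rng()
        self.skip_channels, self.gate_channels, self.inter_channels = (
            skip_channels,
            gate_channels,
            inter,
        )
        self.w_gate = nn.Conv2d(gate_channels, inter, 1, rng=rng)
        self.w_skip = nn.Conv2d(skip_channels, inter, 1, stride=2, bias=False, rng=rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng=rng)
        self.act = nn.ReLU()
        self.up = nn.UpsampleNearest2x()

    def attention_coefficients(self, x: Tensor, g: Tensor) -> Tensor:
        if x.shape[2] != 2 * g.shape[2] or x.shape[3] != 2 * g.shape[3]:
            raise ShapeError(
                f"skip {x.shape[2:]} must be exactly twice the gating signal {g.shape[2:]}"
            )
        s = self.act(self.w_gate(g) + self.w_skip(x))
        alpha = self.psi(s).sigmoid()
        return self.up(alpha)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        return x * self.attention_coefficients(x, g)


class _EncoderStage(nn.Module):
    def __init__(self, in_channels: int, cfg: ArchitectureConfig, level: int, rng):
        super().__init__()
        width = cfg.stage_width(level)
        blocks: list[nn.Module] = []
        if cfg.block_mode in ("serial", "res_only"):
            blocks.append(ResBlock(in_channels, width, cfg.norm, rng))
            dense_in = width
        else:
            dense_in = in_channels
        if cfg.block_mode in ("serial", "dense_only"):
            blocks.append(
                DenseBlock(dense_in, cfg.dense_layers, cfg.stage_growth(level), cfg.norm, rng)
            )
            self.out_channels = blocks[-1].out_channels
        else:
            self.out_channels = width
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class _DecoderStage(nn.Module):
    def __init__(self, in_channels: int, skip_channels: int, cfg: ArchitectureConfig, level: int, rng):
        super().__init__()
        width = cfg.stage_width(level)
        self.up = nn.ConvTranspose2d2x(in_channels, width, rng=rng)
        self.gate = AttentionGate(
            skip_channels, in_channels, cfg.attention_inter_channels, rng=rng
        )
        self.conv1 = nn.Conv2d(width + skip_channels, width, 3, padding=1, rng=rng)
        self.norm1 = _norm_layer(width, cfg.norm)
        self.conv2 = nn.Conv2d(width, width, 3, padding=1, rng=rng)
        self.norm2 = _norm_layer(width, cfg.norm)
        self.act = nn.ReLU()
        self.out_channels = width

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        gated = self.gate(skip, x)
        up = self.up(x)
        y = nn.concatenate([up, gated], axis=1)
        y = self.act(self.norm1(self.conv1(y)))
        return self.act(self.norm2(self.conv2(y)))


class RDAUNet(nn.Module):
    """The full residual-dense-attention U-Net."""

    def __init__(self, config: ArchitectureConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or ArchitectureConfig()
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.pool = nn.MaxPool2d()

        self.encoder_stages: list[_EncoderStage] = []
        channels = cfg.input_channels
        skip_channels: list[int] = []
        for level in range(cfg.depth):
            stage = _EncoderStage(channels, cfg, level, rng)
            self.encoder_stages.append(stage)
            skip_channels.append(stage.out_channels)
            channels = stage.out_channels
        self.bottleneck = _EncoderStage(channels, cfg, cfg.depth, rng)
        channels = self.bottleneck.out_channels

        self.decoder_stages: list[_DecoderStage] = []
        for level in range(cfg.depth - 1, -1, -1):
            stage = _DecoderStage(channels, skip_channels[level], cfg, level, rng)
            self.decoder_stages.append(stage)
            channels = stage.out_channels
        self.head = nn.Conv2d(channels, cfg.output_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.input_channels:
            raise ShapeError(f"expected (N,{cfg.input_channels},H,W), got {x.shape}")
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ShapeError(
                f"expected {cfg.input_size}x{cfg.input_size} input, got {x.shape[2]}x{x.shape[3]}"
            )
        skips: list[Tensor] = []
        for stage in self.encoder_stages:
            x = stage(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for stage, skip in zip(self.decoder_stages, reversed(skips)):
            x = stage(x, skip)
        return self.head(x).sigmoid()

    @property
    def attention_gates(self) -> list[AttentionGate]:
        return [s.gate for s in self.decoder_stages]


# ------------------------------------------------------------------- builders
def build_res_block(
    in_channels: int, out_channels: int, norm: str = "batchnorm", seed: int = 0
) -> ResBlock:
    return ResBlock(in_channels, out_channels, norm, np.random.default_rng(seed))


def build_dense_block(
    in_channels: int, layers: int, growth_rate: int, norm: str = "batchnorm", seed: int = 0
) -> DenseBlock:
    return DenseBlock(in_channels, layers, growth_rate, norm, np.random.default_rng(seed))


def build_attention_gate(
    skip_channels: int, gate_channels: int, inter_channels: int | None = None, seed: int = 0
) -> AttentionGate:
    return AttentionGate(skip_channels, gate_channels, inter_channels, np.random.default_rng(seed))


def build_rda_unet(config: ArchitectureConfig | None = None, seed: int = 0) -> RDAUNet:
    return RDAUNet(config, seed)


def count_parameters(module: nn.Module) -> int:
    """Total trainable parameters (convolution kernels+biases, norm affines)."""
    return module.num_parameters()


def forward(net: RDAUNet, batch: np.ndarray) -> np.ndarray:
    """Run a batch of normalized images through the network (inference mode).

    ``batch`` may be (N, H, W) or (N, C, H, W); returns probability maps of
    shape (N, H, W) for a single output channel.
    """
    arr = np.asarray(batch, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, None]
    was_training = net.training
    net.eval()
    out = net(Tensor(arr)).data
    if was_training:
        net.train()
    if out.shape[1] == 1:
        out = out[:, 0]
    return out


def describe(net: nn.Module, input_shape: tuple[int, ...] | None = None) -> str:
    """Per-node manifest as TSV: node, type, out_shape, params.

    When ``input_shape`` is omitted for an :class:`RDAUNet`, a single dummy
    input at the configured size is traced.
    """
    if input_shape is None:
        if not isinstance(net, RDAUNet):
            raise ValueError("input_shape required for non-RDAUNet modules")
        cfg = net.config
        input_shape = (1, cfg.input_channels, cfg.input_size, cfg.input_size)
    names = {id(mod): name for name, mod in net.named_modules()}
    was_training = net.training
    net.eval()
    with nn.trace() as rows:
        net(Tensor(np.zeros(input_shape)))
    if was_training:
        net.train()
    buf = io.StringIO()
    buf.write("node\ttype\tout_shape\tparams\n")
    total = 0
    for mod, shape in rows:
        n_par = sum(p.size for _, p in mod.named_parameters())
        total += n_par
        buf.write(
            f"{names.get(id(mod), '?')}\t{type(mod).__name__}\t"
            f"{'x'.join(map(str, shape))}\t{n_par}\n"
        )
    buf.write(f"TOTAL\t\t\t{net.num_parameters()}\n")
    return buf.getvalue()
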