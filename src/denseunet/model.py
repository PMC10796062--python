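"""Dense-block U-Net for 2D multimodal tumor segmentation.

The network keeps the U-Net encoder/decoder skeleton but replaces every
convolution block with a dense block: layer i inside a block receives the
channel concatenation of the block input and all previous layer outputs,
and each layer is the composite BN -> ReLU -> 3x3 conv emitting
``growth_rate`` channels.  A block therefore leaves with
``in + block_depth * growth_rate`` channels.  Between encoder blocks a
transition layer (BN -> ReLU -> 1x1 conv -> 2x2 average pooling) compresses
channels to ``floor(compression * c)`` and halves both spatial dims.  The
decoder mirrors the encoder with 2x transposed-convolution upsampling and
concatenation skip connections from each encoder block to the same-scale
decoder block; the head is a 1x1 convolution to ``out_classes`` followed by
a per-pixel softmax, so the output is a categorical distribution over the
four tumor label classes at every pixel.

Channel bookkeeping is computed up front (:func:`plan_channels`) and is the
single source of truth for layer construction, so a traced forward pass can
be checked against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .containers import RegionMasks, SliceSample, ValidationError
from .layers import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    Module,
    ReLU,
    Sequential,
)
from .preprocess import labels_to_regions

#: Softmax class index -> tumor label value.
CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)


@dataclass(frozen=True)
class DenseUnetConfig:
    """Architecture hyperparameters.

    ``block_depth`` is the number of dense layers L per block and
    ``growth_rate`` the channels each layer adds to the concatenation;
    ``compression`` is the transition-layer channel compression factor
    (called theta here; the Tversky loss owns the name alpha).  Input
    spatial dims must be divisible by ``2**(n_scales - 1)``.
    """

    in_channels: int = 4
    n_scales: int = 5
    block_depth: int = 4
    growth_rate: int = 16
    compression: float = 0.5
    stem_channels: int = 32
    out_classes: int = 4
    upsample: str = "transposed"  # or "nearest" (nearest + 1x1 conv)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.compression <= 1.0:
            raise ValidationError(f"compression must be in (0, 1], got {self.compression}")
        if self.block_depth < 1:
            raise ValidationError(f"block_depth must be >= 1, got {self.block_depth}")
        if self.n_scales < 2:
            raise ValidationError(f"n_scales must be >= 2, got {self.n_scales}")
        if min(self.in_channels, self.growth_rate, self.stem_channels, self.out_classes) < 1:
            raise ValidationError("channel counts must be positive")
        if self.upsample not in ("transposed", "nearest"):
            raise ValidationError(f"unknown upsample mode {self.upsample!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DenseUnetConfig":
        return cls(**d)


#: Compact configuration for fast experiments and the smoke preset.
SMALL_CONFIG = DenseUnetConfig(
    n_scales=3, block_depth=2, growth_rate=8, stem_channels=16
)


@dataclass
class LayerSpec:
    """Per-stage channel counts derived from a :class:`DenseUnetConfig`.

    ``encoder_blocks``/``decoder_blocks`` hold (in, out) pairs per scale;
    ``transitions`` the encoder (in, out) compressions; ``decoder_up`` the
    (in, out) of each upsampling step; ``skips`` the encoder block outputs
    consumed by the decoder (shallowest first).
    """

    stem_out: int
    encoder_blocks: list[tuple[int, int]] = field(default_factory=list)
    transitions: list[tuple[int, int]] = field(default_factory=list)
    bottleneck: tuple[int, int] = (0, 0)
    skips: list[int] = field(default_factory=list)
    decoder_up: list[tuple[int, int]] = field(default_factory=list)
    decoder_blocks: list[tuple[int, int]] = field(default_factory=list)
    head_in: int = 0


def plan_channels(config: DenseUnetConfig) -> LayerSpec:
    """Derive every stage's channel counts from the concatenation arithmetic.

    Dense blocks add ``block_depth * growth_rate`` channels; transitions
    and upsampling steps compress to ``floor(compression * c)``.
    """
    config.validate()
    add = config.block_depth * config.growth_rate
    spec = LayerSpec(stem_out=config.stem_channels)
    c = config.stem_channels
    for _ in range(config.n_scales - 1):
        spec.encoder_blocks.append((c, c + add))
        c += add
        spec.skips.append(c)
        out = max(1, int(np.floor(config.compression * c)))
        spec.transitions.append((c, out))
        c = out
    spec.bottleneck = (c, c + add)
    c += add
    for skip in reversed(spec.skips):
        up_out = max(1, int(np.floor(config.compression * c)))
        spec.decoder_up.append((c, up_out))
        c = up_out + skip
        spec.decoder_blocks.append((c, c + add))
        c += add
    spec.head_in = c
    return spec


class DenseLayer(Module):
    """BN -> ReLU -> 3x3 conv emitting ``growth_rate`` channels."""

    def __init__(self, in_ch: int, growth_rate: int, rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm2d(in_ch)
        self.act = ReLU()
        self.conv = Conv2d(in_ch, growth_rate, kernel=3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.act(self.bn(x)))


class DenseBlock(Module):
    """Concatenating stack of dense layers: out = [x0, x1, ..., xL]."""

    def __init__(self, in_ch: int, block_depth: int, growth_rate: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_ch = in_ch
        self.out_ch = in_ch + block_depth * growth_rate
        self.dense_layers = [
            DenseLayer(in_ch + i * growth_rate, growth_rate, rng)
            for i in range(block_depth)
        ]

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for layer in self.dense_layers:
            y = layer(feats[0] if len(feats) == 1 else ag.concat(feats, axis=1))
            feats.append(y)
        return ag.concat(feats, axis=1)


class TransitionDown(Module):
    """BN -> ReLU -> 1x1 conv (compress) -> 2x2 average pool (halve dims)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.body = Sequential(
            BatchNorm2d(in_ch),
            ReLU(),
            Conv2d(in_ch, out_ch, kernel=1, rng=rng),
            AvgPool2d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _NearestUp(Module):
    """Nearest-neighbour 2x upsampling followed by a 1x1 conv."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        # repeat each pixel into a 2x2 patch via the transposed-conv primitive
        # with a fixed all-ones kernel would re-learn it; use autograd-safe repeat
        up = _repeat2x(x)
        return self.conv(up)


def _repeat2x(x: Tensor) -> Tensor:
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        n, c, h2, w2 = g.shape
        x._accumulate(
            g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        )

    return Tensor._make(data, (x,), bwd)


class DenseUnet(Module):
    """Encoder-decoder segmentation network with dense convolution blocks."""

    def __init__(self, config: DenseUnetConfig):
        super().__init__()
        config.validate()
        self.config = config
        self.spec = plan_channels(config)
        rng = np.random.default_rng(config.seed)
        d, g = config.block_depth, config.growth_rate

        self.stem = Conv2d(config.in_channels, config.stem_channels, kernel=3, rng=rng)
        self.enc_blocks = [
            DenseBlock(cin, d, g, rng) for cin, _ in self.spec.encoder_blocks
        ]
        self.trans_down = [
            TransitionDown(cin, cout, rng) for cin, cout in self.spec.transitions
        ]
        self.bottleneck = DenseBlock(self.spec.bottleneck[0], d, g, rng)
        if config.upsample == "transposed":
            self.ups = [ConvTranspose2x2(cin, cout, rng) for cin, cout in self.spec.decoder_up]
        else:
            self.ups = [_NearestUp(cin, cout, rng) for cin, cout in self.spec.decoder_up]
        self.dec_blocks = [
            DenseBlock(cin, d, g, rng) for cin, _ in self.spec.decoder_blocks
        ]
        self.head = Conv2d(self.spec.head_in, config.out_classes, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, in_channels, H, W) -> (N, out_classes, H, W) class probabilities."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        div = 2 ** (self.config.n_scales - 1)
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValidationError(
                f"expected {self.config.in_channels} input channels, got {c}"
            )
        if h % div or w % div:
            raise ValidationError(
                f"input spatial dims ({h}, {w}) must be divisible by {div} "
                f"for n_scales={self.config.n_scales}"
            )
        y = self.stem(x)
        skips = []
        for block, down in zip(self.enc_blocks, self.trans_down):
            y = block(y)
            skips.append(y)
            y = down(y)
        y = self.bottleneck(y)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            y = up(y)
            y = ag.concat([y, skip], axis=1)
            y = block(y)
        logits = self.head(y)
        return ag.softmax(logits, axis=1)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_denseunet(config: DenseUnetConfig | None = None) -> DenseUnet:
    """Construct a seeded network from a config (defaults if omitted)."""
    return DenseUnet(config or DenseUnetConfig())


def predict_labels(network: DenseUnet, sample: SliceSample | np.ndarray
                   ) -> tuple[RegionMasks, np.ndarray]:
    """Segment one slice: argmax class map -> labels {0,1,2,4} -> region masks.

    Region nesting ET <= TC <= WT holds by construction because the masks
    are derived from a single label map.
    """
    image = sample.image if isinstance(sample, SliceSample) else np.asarray(sample)
    if image.ndim != 3:
        raise ValidationError(f"expected a (channels, h, w) slice, got {image.shape}")
    network.eval()
    probs = network(Tensor(image[None].astype(np.float32)))
    class_idx = np.argmax(probs.data[0], axis=0)
    labels = CLASS_TO_LABEL[class_idx]
    return labels_to_regions(labels), labels
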