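"""UNet3+ architecture specification and exact parameter accounting.

The segmentation network is a UNet3+ — an encoder-decoder with full-scale
skip connections, in which every decoder stage aggregates feature maps
from *all* encoder levels (max-pooled down) and all deeper decoder stages
(upsampled), each routed through a 3x3 skip convolution to a common width,
concatenated, and fused by a 3x3 convolution — over a frozen VGG16
convolutional encoder with ImageNet-configuration widths
(64, 128, 256, 512, 512).

The published configuration is under-determined by its description alone;
the free elements are fixed here by the published parameter budget and
held constant across variants:

* the full VGG16 convolutional backbone is always instantiated and frozen
  (14,714,688 parameters in both variants, the first ``n_stacks`` blocks
  feeding the decoder);
* a pooled bottleneck stage of three 3x3 convolutions at width 640 acts
  as the deepest "down-sampling stack";
* canonical UNet3+ decoder constants: 64-channel skip convolutions and
  320-channel fusion convolutions;
* a 1x1 softmax head.

With ``n_stacks = 5`` and six output classes this gives 36.07 M total
parameters (21.35 M trainable); with ``n_stacks = 4`` and three classes,
32.27 M total (17.55 M trainable) — the frozen count is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ModelSpec",
    "LayerSpec",
    "ParameterCounts",
    "VGG16_BLOCKS",
    "unet3plus_layers",
    "parameter_counts",
]

#: VGG16 convolutional configuration: (width, n_convs) per block
VGG16_BLOCKS: tuple[tuple[int, int], ...] = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

SKIP_CHANNELS = 64
FUSION_CHANNELS = 320
BOTTLENECK_WIDTH = 640
BOTTLENECK_CONVS = 3


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one segmentation model.

    ``n_stacks`` is the number of down-/up-sampling stacks (5 for the
    six-class model, 4 for the three-class variant); the encoder is a
    frozen VGG16 whose first ``n_stacks`` blocks feed the decoder.
    ``width_factor < 1`` selects a reduced-width desk-scale variant with a
    trainable encoder — flagged via ``desk_scale`` and never used for
    parameter-count checks.
    """

    n_classes: int = 6
    input_px: int = 224
    n_stacks: int = 5
    backbone: str = "vgg16"
    activation: str = "relu"
    width_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.width_factor == 1.0 and self.n_stacks not in (4, 5):
            raise ValueError(f"n_stacks must be 4 or 5 at full scale, got {self.n_stacks}")
        if not (1 <= self.n_stacks <= len(VGG16_BLOCKS)):
            raise ValueError(f"n_stacks must be in [1, 5], got {self.n_stacks}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0 < self.width_factor <= 1):
            raise ValueError("width_factor must be in (0, 1]")

    @property
    def desk_scale(self) -> bool:
        return self.width_factor < 1.0


@dataclass(frozen=True)
class LayerSpec:
    """One parameterized layer in the network graph."""

    name: str
    kind: str
    in_channels: int
    out_channels: int
    kernel: int
    trainable: bool

    @property
    def n_params(self) -> int:
        return self.kernel * self.kernel * self.in_channels * self.out_channels + self.out_channels


@dataclass(frozen=True)
class ParameterCounts:
    total: int
    trainable: int
    frozen: int

    @property
    def total_millions(self) -> float:
        return round(self.total / 1e6, 1)

    @property
    def trainable_millions(self) -> float:
        return round(self.trainable / 1e6, 1)

    @property
    def frozen_millions(self) -> float:
        return round(self.frozen / 1e6, 1)


def vgg16_layers(trainable: bool = False) -> list[LayerSpec]:
    """The 13 convolutional layers of VGG16 (ImageNet widths)."""
    layers = []
    cin = 3
    for b, (width, n_convs) in enumerate(VGG16_BLOCKS, start=1):
        for i in range(1, n_convs + 1):
            layers.append(
                LayerSpec(f"block{b}_conv{i}", "conv", cin, width, 3, trainable)
            )
            cin = width
    return layers


def unet3plus_layers(spec: ModelSpec) -> list[LayerSpec]:
    """Full layer graph of the UNet3+ configuration for ``spec``.

    Only applicable to the full-scale architecture (``width_factor = 1``);
    the reduced desk-scale variant has its own trainable graph and is
    excluded from parameter-count checks.
    """
    if spec.desk_scale:
        raise ValueError("parameter-count graph is defined for the full-scale model only")
    layers = vgg16_layers(trainable=False)  # full backbone always present, frozen

    tap_widths = [w for w, _ in VGG16_BLOCKS][: spec.n_stacks]
    # pooled bottleneck stage = the deepest down-sampling stack
    cin = tap_widths[-1]
    for i in range(1, BOTTLENECK_CONVS + 1):
        layers.append(LayerSpec(f"bottleneck_conv{i}", "conv", cin, BOTTLENECK_WIDTH, 3, True))
        cin = BOTTLENECK_WIDTH

    # decoder: levels 0 .. n_stacks-1 (level i at the scale of encoder tap i),
    # bottleneck at level n_stacks; stages run deep -> shallow
    n = spec.n_stacks
    chan = {n: BOTTLENECK_WIDTH}
    for i in range(n):
        chan[i] = tap_widths[i]
    dec_chan: dict[int, int] = {}
    for j in range(n - 1, -1, -1):
        sources = []
        for lev in range(0, j + 1):  # encoder taps at or above this scale
            sources.append(("enc", lev, chan[lev]))
        for lev in range(j + 1, n):  # deeper decoder stages
            sources.append(("dec", lev, dec_chan[lev]))
        sources.append(("bott", n, BOTTLENECK_WIDTH))
        for origin, lev, c in sources:
            layers.append(
                LayerSpec(f"de{j}_skip_{origin}{lev}", "conv", c, SKIP_CHANNELS, 3, True)
            )
        agg = SKIP_CHANNELS * len(sources)
        layers.append(LayerSpec(f"de{j}_fusion", "conv", agg, FUSION_CHANNELS, 3, True))
        dec_chan[j] = FUSION_CHANNELS

    layers.append(LayerSpec("head", "conv", FUSION_CHANNELS, spec.n_classes, 1, True))
    return layers


def parameter_counts(spec_or_layers) -> ParameterCounts:
    """Total / trainable / frozen parameter counts for a model spec or layer list."""
    layers = (
        unet3plus_layers(spec_or_layers)
        if isinstance(spec_or_layers, ModelSpec)
        else list(spec_or_layers)
    )
    trainable = sum(l.n_params for l in layers if l.trainable)
    frozen = sum(l.n_params for l in layers if not l.trainable)
    return ParameterCounts(total=trainable + frozen, trainable=trainable, frozen=frozen)
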