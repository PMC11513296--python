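"""VP-Net: a lightweight CNN that regresses SAW velocity from one slice.

The network maps a normalised raw phase slice (lateral x time, values in
[0, 1]) to a single non-negative wave velocity in m/s.  It stacks five
convolution-batchnorm-ReLU (CBR) blocks — the first with an 11x11
kernel and stride 4, acting as a learned overlapping patch extractor
with a large receptive field — interleaved after the third block with
depthwise-separable convolution blocks (channel-preserving, cheap) and
squeeze-and-excitation (SE) channel gates, followed by global average
pooling and a single linear output unit.  Three size variants (S/B/L)
differ only in their filter-count schedules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    GlobalAvgPool,
    Layer,
    ReLU,
    Sequential,
    SqueezeExcite,
    same_pad,
)

__all__ = [
    "VPNetVariant",
    "VARIANTS",
    "ModelSummary",
    "cbr_block",
    "separable_conv_block",
    "se_block",
    "build_vpnet",
    "VPNet",
    "summarize",
]


@dataclass(frozen=True)
class VPNetVariant:
    """Filter-count schedule defining one VP-Net size."""

    name: str
    fs_cbr: tuple[int, int, int, int, int]
    fs_scb: tuple[int, int, int]

    def __post_init__(self):
        if self.fs_scb != (self.fs_cbr[2], self.fs_cbr[3], self.fs_cbr[4]):
            raise ValueError(
                "separable-block filter counts must match the channel counts of "
                f"CBR3..CBR5; got fs_scb={self.fs_scb}, fs_cbr={self.fs_cbr}"
            )


VARIANTS: dict[str, VPNetVariant] = {
    "S": VPNetVariant("S", (16, 16, 16, 32, 64), (16, 32, 64)),
    "B": VPNetVariant("B", (16, 16, 32, 64, 128), (32, 64, 128)),
    "L": VPNetVariant("L", (32, 32, 64, 128, 256), (64, 128, 256)),
}

#: Kernel size and stride of the five CBR blocks, in order.
CBR_SPECS = ((11, 4), (3, 1), (7, 2), (7, 2), (3, 1))


def cbr_block(in_ch: int, filters: int, kernel: int, stride: int, rng, tag: str) -> list[Layer]:
    """Convolution -> batch norm -> ReLU."""
    return [
        Conv2D(in_ch, filters, kernel, stride, rng=rng, name=f"{tag}_conv"),
        BatchNorm(filters, name=f"{tag}_bn"),
        ReLU(name=f"{tag}_relu"),
    ]


def separable_conv_block(channels: int, rng, tag: str) -> list[Layer]:
    """Depthwise 3x3 then pointwise 1x1, each BN + ReLU; channels preserved."""
    return [
        DepthwiseConv2D(channels, 3, rng=rng, name=f"{tag}_dw"),
        BatchNorm(channels, name=f"{tag}_bn1"),
        ReLU(name=f"{tag}_relu1"),
        Conv2D(channels, channels, 1, 1, rng=rng, name=f"{tag}_pw"),
        BatchNorm(channels, name=f"{tag}_bn2"),
        ReLU(name=f"{tag}_relu2"),
    ]


def se_block(channels: int, rng, tag: str) -> list[Layer]:
    """Squeeze-and-excitation gate with a C/4 bottleneck."""
    return [SqueezeExcite(channels, rng=rng, name=tag)]


def _build_layers(variant: VPNetVariant, rng) -> list[Layer]:
    f = variant.fs_cbr
    s = variant.fs_scb
    layers: list[Layer] = []
    layers += cbr_block(1, f[0], CBR_SPECS[0][0], CBR_SPECS[0][1], rng, "cbr1")
    layers += cbr_block(f[0], f[1], CBR_SPECS[1][0], CBR_SPECS[1][1], rng, "cbr2")
    layers += cbr_block(f[1], f[2], CBR_SPECS[2][0], CBR_SPECS[2][1], rng, "cbr3")
    layers += separable_conv_block(s[0], rng, "sep1")
    layers += se_block(s[0], rng, "se1")
    layers += cbr_block(f[2], f[3], CBR_SPECS[3][0], CBR_SPECS[3][1], rng, "cbr4")
    layers += separable_conv_block(s[1], rng, "sep2")
    layers += se_block(s[1], rng, "se2")
    layers += cbr_block(f[3], f[4], CBR_SPECS[4][0], CBR_SPECS[4][1], rng, "cbr5")
    layers += separable_conv_block(s[2], rng, "sep3")
    layers += se_block(s[2], rng, "se3")
    layers += [GlobalAvgPool(name="gap"), Dense(f[4], 1, rng=rng, name="head")]
    return layers


class VPNet:
    """A built VP-Net: Sequential stack plus the inference contract.

    ``predict`` runs in evaluation mode (batch-norm running statistics)
    and clamps the scalar output at zero, since wave velocity is
    non-negative by definition.
    """

    def __init__(self, variant: VPNetVariant, seed: int = 0):
        self.variant = variant
        rng = np.random.default_rng(seed)
        self.model = Sequential(_build_layers(variant, rng), name=f"vpnet-{variant.name}")

    def forward(self, x: np.ndarray, training: bool = False, record: bool = False) -> np.ndarray:
        return self.model.forward(x, training=training, record=record)[:, 0]

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size], training=False))
        return np.maximum(np.concatenate(out), 0.0)

    # --- probe addressing for activation mapping -----------------------
    def conv_layer_names(self) -> list[str]:
        """Names of 2-D convolution layers (pointwise included,
        depthwise excluded), in forward order."""
        return [l.name for l in self.model.layers if isinstance(l, Conv2D)]

    def resolve_probe(self, probe: str) -> str:
        """Map a probe id to a layer name.

        Accepts block addressing ('cbr1'..'cbr5' -> that block's
        convolution) or index addressing ('conv1', 'conv3', ... over the
        Conv2D enumeration), or an exact layer name.
        """
        if probe.startswith("cbr") and len(probe) == 4:
            name = f"{probe}_conv"
            if any(l.name == name for l in self.model.layers):
                return name
        if probe.startswith("conv") and probe[4:].isdigit():
            idx = int(probe[4:]) - 1
            names = self.conv_layer_names()
            if 0 <= idx < len(names):
                return names[idx]
            raise KeyError(f"conv index {probe} out of range (1..{len(names)})")
        if any(l.name == probe for l in self.model.layers):
            return probe
        raise KeyError(f"unknown probe layer {probe!r}")


@dataclass
class ModelSummary:
    """Deterministic parameter and multiply-add accounting."""

    parameter_count: int
    flops: int  # multiply-add count at the given input size
    layer_table: list[tuple[str, str, tuple, int, int]]  # name, type, out shape, params, MACs

    def __str__(self) -> str:
        lines = [f"{'layer':<12} {'type':<16} {'output':<18} {'params':>10} {'MACs':>14}"]
        for name, typ, shape, p, m in self.layer_table:
            lines.append(f"{name:<12} {typ:<16} {str(shape):<18} {p:>10} {m:>14}")
        lines.append(f"total params: {self.parameter_count:,}   total MACs: {self.flops:,}")
        return "\n".join(lines)


def _layer_cost(layer: Layer, shape: tuple[int, int, int]) -> tuple[tuple, int]:
    """(output shape, multiply-add count) for one layer at input shape (H,W,C)."""
    h, w, c = shape
    if isinstance(layer, Conv2D):
        ho, _, _ = same_pad(h, layer.k, layer.s)
        wo, _, _ = same_pad(w, layer.k, layer.s)
        return (ho, wo, layer.out_ch), ho * wo * layer.k * layer.k * layer.in_ch * layer.out_ch
    if isinstance(layer, DepthwiseConv2D):
        return (h, w, c), h * w * layer.k * layer.k * c
    if isinstance(layer, BatchNorm):
        return (h, w, c), h * w * c
    if isinstance(layer, ReLU):
        return (h, w, c), 0
    if isinstance(layer, SqueezeExcite):
        hidden = layer.c // 4
        return (h, w, c), c * hidden * 2 + h * w * c
    if isinstance(layer, GlobalAvgPool):
        return (1, 1, c), h * w * c
    if isinstance(layer, Dense):
        return (1, 1, layer.params["w"].shape[1]), layer.params["w"].size
    raise TypeError(f"unknown layer type {type(layer)}")  # pragma: no cover


def summarize(net: VPNet, input_size: int = 320) -> ModelSummary:
    """Per-layer and total parameter / multiply-add accounting."""
    shape = (input_size, input_size, 1)
    table = []
    total_macs = 0
    for layer in net.model.layers:
        out_shape, macs = _layer_cost(layer, shape)
        table.append((layer.name, type(layer).__name__, out_shape, layer.n_params(), macs))
        total_macs += macs
        shape = out_shape
    return ModelSummary(
        parameter_count=net.model.n_params(), flops=int(total_macs), layer_table=table
    )


def build_vpnet(variant: str | VPNetVariant = "B", seed: int = 0) -> VPNet:
    """Construct a VP-Net of the requested size with seeded weights."""
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant.upper()]
        except KeyError:
            raise ValueError(f"unknown variant {variant!r}; choose from S, B, L") from None
    return VPNet(variant, seed=seed)
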