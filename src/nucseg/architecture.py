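"""Declarative specification of the residual-skip nuclear segmentation network.

The network is a VGG-style encoder-decoder: four encoder blocks
(2, 2, 3, 3 conv+BN+ReLU units) each followed by a 2x2 max-pool, mirrored by
four decoder blocks preceded by max-unpooling, for 20 convolution layers in
total (the last one being the 2-channel classifier conv).  Four residual skip
links carry the output of the *first* conv unit of each encoder block to an
element-wise addition just before the *last* conv unit of the matching decoder
block.  This module only describes the architecture; the runnable network is
built from an :class:`ArchitectureSpec` by :mod:`nucseg.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ParameterAccount",
    "rsnn_spec",
    "count_parameters",
    "trace_shapes",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: channel widths of the four encoder blocks at full width
_BLOCK_WIDTHS = (64, 128, 256, 512)
#: number of conv+BN+ReLU units per encoder block
_BLOCK_DEPTHS = (2, 2, 3, 3)

KINDS = ("conv", "maxpool", "unpool", "add", "classifier")


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table.

    ``kind`` is one of ``conv`` (conv 3x3 + BN + ReLU), ``maxpool`` (2x2
    stride 2, indices recorded), ``unpool`` (max-unpool paired with
    ``pair``), ``add`` (element-wise skip addition / concatenation sink) and
    ``classifier`` (conv 3x3 + BN, softmax applied afterwards).
    ``skip_tag`` marks a layer as the source (on conv) or sink (on add) of a
    residual connection RC-1..RC-4.
    """

    name: str
    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple[int, int] = (3, 3)
    skip_tag: str | None = None
    pair: str | None = None  # unpool -> name of the paired maxpool

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "classifier"):
            if self.in_channels <= 0 or self.out_channels <= 0:
                raise ValueError(f"{self.name}: channel counts must be positive")


def _scale(channels: int, width: Fraction) -> int:
    scaled = int(channels * width)
    if scaled < 1:
        raise ValueError(
            f"width multiplier {width} collapses {channels} channels to zero"
        )
    return scaled


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer list plus the knobs that parameterize it."""

    layers: tuple[LayerSpec, ...]
    skip_mode: str = "add"  # none | add | concat
    width_multiplier: Fraction = Fraction(1)
    n_classes: int = 2

    @property
    def conv_layers(self) -> tuple[LayerSpec, ...]:
        return tuple(l for l in self.layers if l.kind in ("conv", "classifier"))

    @property
    def skip_links(self) -> tuple[str, ...]:
        return tuple(
            l.skip_tag for l in self.layers if l.kind == "add" and l.skip_tag
        )


def rsnn_spec(
    width_multiplier: float | Fraction = 1,
    skip_mode: str = "add",
    n_classes: int = 2,
) -> ArchitectureSpec:
    """Build the architecture table of the 20-conv-layer network.

    ``width_multiplier`` scales every hidden channel count (input stays 3,
    output stays ``n_classes``); ``skip_mode`` selects identity addition
    (default), channel concatenation, or no skips at all.  Concatenation
    doubles the input width of the conv unit that follows each sink.
    """
    if skip_mode not in ("none", "add", "concat"):
        raise ValueError(f"unknown skip_mode {skip_mode!r}")
    width = Fraction(width_multiplier).limit_denominator(4096)
    if width <= 0:
        raise ValueError("width_multiplier must be positive")

    w = [_scale(c, width) for c in _BLOCK_WIDTHS]
    layers: list[LayerSpec] = []

    # ---- encoder ----
    in_ch = 3
    for b, (width_b, depth) in enumerate(zip(w, _BLOCK_DEPTHS), start=1):
        for u in range(1, depth + 1):
            layers.append(
                LayerSpec(
                    name=f"EConvBR-{b}_{u}",
                    kind="conv",
                    in_channels=in_ch,
                    out_channels=width_b,
                    skip_tag=f"RC-{b}" if (u == 1 and skip_mode != "none") else None,
                )
            )
            in_ch = width_b
        layers.append(LayerSpec(name=f"Pool-{b}", kind="maxpool"))

    # ---- decoder (mirror) ----
    for b in range(4, 0, -1):
        width_b = w[b - 1]
        depth = _BLOCK_DEPTHS[b - 1]
        layers.append(LayerSpec(name=f"Unpool-{b}", kind="unpool", pair=f"Pool-{b}"))
        # units depth..2 keep the block width; the add sits after unit 2
        for u in range(depth, 1, -1):
            layers.append(
                LayerSpec(
                    name=f"DConvBR-{b}_{u}",
                    kind="conv",
                    in_channels=in_ch,
                    out_channels=width_b,
                )
            )
            in_ch = width_b
        if skip_mode != "none":
            layers.append(
                LayerSpec(name=f"Add-{b}", kind="add", skip_tag=f"RC-{b}")
            )
            if skip_mode == "concat":
                in_ch = in_ch + width_b
        # final unit of the block transitions to the next block's width
        out_ch = w[b - 2] if b > 1 else n_classes
        layers.append(
            LayerSpec(
                name=f"DConvBR-{b}_1",
                kind="conv" if b > 1 else "classifier",
                in_channels=in_ch,
                out_channels=out_ch,
            )
        )
        in_ch = out_ch

    return ArchitectureSpec(
        layers=tuple(layers),
        skip_mode=skip_mode,
        width_multiplier=width,
        n_classes=n_classes,
    )


def spec_to_yaml(spec: ArchitectureSpec, path=None) -> str:
    """Serialize an architecture spec (layer list + knobs) to YAML."""
    import yaml

    doc = {
        "skip_mode": spec.skip_mode,
        "width_multiplier": [spec.width_multiplier.numerator,
                             spec.width_multiplier.denominator],
        "n_classes": spec.n_classes,
        "layers": [
            {k: v for k, v in dict(
                name=l.name, kind=l.kind, in_channels=l.in_channels,
                out_channels=l.out_channels, kernel=list(l.kernel),
                skip_tag=l.skip_tag, pair=l.pair).items() if v not in (None, 0)}
            for l in spec.layers
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> ArchitectureSpec:
    """Load an architecture spec from a YAML string or file path."""
    import os
    import yaml

    if isinstance(source, str) and "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    layers = tuple(
        LayerSpec(
            name=l["name"], kind=l["kind"],
            in_channels=l.get("in_channels", 0),
            out_channels=l.get("out_channels", 0),
            kernel=tuple(l.get("kernel", (3, 3))),
            skip_tag=l.get("skip_tag"), pair=l.get("pair"),
        )
        for l in doc["layers"]
    )
    num, den = doc["width_multiplier"]
    return ArchitectureSpec(layers=layers, skip_mode=doc["skip_mode"],
                            width_multiplier=Fraction(num, den),
                            n_classes=doc["n_classes"])


@dataclass
class ParameterAccount:
    """Per-layer trainable-parameter ledger.

    ``rows`` holds (layer name, conv weight+bias count, BN scale+shift count);
    conv = k_h*k_w*C_in*C_out + C_out, BN = 2*C_out.
    """

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(conv + bn for _, conv, bn in self.rows)

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {name: (conv, bn) for name, conv, bn in self.rows}


def count_parameters(spec: ArchitectureSpec) -> ParameterAccount:
    """Closed-form trainable-parameter account of an architecture spec."""
    account = ParameterAccount()
    for layer in spec.layers:
        if layer.kind in ("conv", "classifier"):
            kh, kw = layer.kernel
            conv = kh * kw * layer.in_channels * layer.out_channels + layer.out_channels
            bn = 2 * layer.out_channels
            account.rows.append((layer.name, conv, bn))
    return account


def trace_shapes(
    spec: ArchitectureSpec, input_hw: tuple[int, int]
) -> list[tuple[str, int, int, int]]:
    """Walk the layer list and report (name, H, W, C) after every layer.

    Pooling halves spatial dims with floor rounding (125 -> 62); each unpool
    restores the recorded pre-pool size of its paired pool (62 -> 125), so odd
    sizes round-trip exactly as in the reference feature-map trace.
    """
    h, w = input_hw
    if h < 16 or w < 16:
        raise ValueError("input must be at least 16x16 to survive 4 pooling stages")
    c = 3
    pre_pool: dict[str, tuple[int, int]] = {}
    skip_channels: dict[str, int] = {}
    trace: list[tuple[str, int, int, int]] = []
    for layer in spec.layers:
        if layer.kind in ("conv", "classifier"):
            if layer.in_channels != c:
                raise ValueError(
                    f"{layer.name}: expects {layer.in_channels} channels, got {c}"
                )
            c = layer.out_channels
            if layer.skip_tag:
                skip_channels[layer.skip_tag] = c
        elif layer.kind == "maxpool":
            pre_pool[layer.name] = (h, w)
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for 4 pooling stages")
        elif layer.kind == "unpool":
            h, w = pre_pool[layer.pair]
        elif layer.kind == "add":
            src = skip_channels.get(layer.skip_tag, c)
            if spec.skip_mode == "concat":
                c = c + src
            elif src != c:
                raise ValueError(
                    f"{layer.name}: skip shape mismatch ({src} vs {c} channels)"
                )
        trace.append((layer.name, h, w, c))
    return trace
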