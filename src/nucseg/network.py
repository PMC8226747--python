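"""Runnable segmentation network assembled from an :class:`ArchitectureSpec`.

The graph is a straight line with four side branches: each encoder block's
first conv unit taps its activation into a residual store, and each decoder
block adds (or concatenates) that tensor back in just before the block's last
conv unit.  Backpropagation walks the same list in reverse, accumulating skip
gradients into the encoder taps.
"""

from __future__ import annotations

import numpy as np

from .architecture import ArchitectureSpec, rsnn_spec, trace_shapes
from . import nn

__all__ = ["SegmentationNetwork", "build_rsnn", "apply_skip"]


def apply_skip(local: np.ndarray, transferred: np.ndarray,
               mode: str = "add") -> np.ndarray:
    """Combine decoder-local features with encoder-transferred features.

    ``add`` is the identity-mapping element-wise sum (shapes must match);
    ``concat`` stacks channels (spatial dims must match).
    """
    if mode == "add":
        return nn.Add.forward(local, transferred)
    if mode == "concat":
        return nn.Concat.forward(local, transferred)
    raise ValueError(f"unknown skip mode {mode!r}")


class _ConvUnit:
    """conv 3x3 -> BN -> (optional ReLU); the classifier unit omits the ReLU."""

    def __init__(self, spec_layer, rng, dtype, relu: bool):
        self.name = spec_layer.name
        self.conv = nn.Conv2d(spec_layer.in_channels, spec_layer.out_channels,
                              rng, spec_layer.name, dtype)
        self.bn = nn.BatchNorm2d(spec_layer.out_channels, spec_layer.name, dtype)
        self.relu = nn.ReLU() if relu else None
        self.skip_tag = spec_layer.skip_tag

    @property
    def parameters(self):
        return self.conv.parameters + self.bn.parameters

    def forward(self, x, training):
        y = self.bn.forward(self.conv.forward(x, training), training)
        if self.relu is not None:
            y = self.relu.forward(y, training)
        return y

    def backward(self, dy):
        if self.relu is not None:
            dy = self.relu.backward(dy)
        return self.conv.backward(self.bn.backward(dy))


class SegmentationNetwork:
    """The encoder-decoder network, built layer-for-layer from a spec."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 dtype=np.float32, unpool_mode: str = "indices"):
        trace_shapes(spec, (16, 16))  # validates channel/skip wiring
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.nodes: list[tuple[str, object]] = []
        pools: dict[str, nn.MaxPool2x2] = {}
        for layer in spec.layers:
            if layer.kind in ("conv", "classifier"):
                unit = _ConvUnit(layer, rng, dtype, relu=layer.kind == "conv")
                self.nodes.append(("conv", unit))
            elif layer.kind == "maxpool":
                pool = nn.MaxPool2x2()
                pools[layer.name] = pool
                self.nodes.append(("pool", pool))
            elif layer.kind == "unpool":
                self.nodes.append(
                    ("unpool", nn.MaxUnpool2x2(pools[layer.pair], unpool_mode)))
            elif layer.kind == "add":
                op = nn.Add() if spec.skip_mode == "add" else nn.Concat()
                self.nodes.append(("skip", (op, layer.skip_tag)))

    # ---- parameter access ----
    @property
    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for kind, node in self.nodes:
            if kind == "conv":
                params.extend(node.parameters)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for kind, _ in self.nodes if kind == "conv")

    @property
    def n_skips(self) -> int:
        return sum(1 for kind, _ in self.nodes if kind == "skip")

    # ---- forward / backward ----
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the graph on an NHWC batch; returns pre-softmax maps."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("expected an NHWC batch")
        taps: dict[str, np.ndarray] = {}
        self._skip_state: list[tuple[str, int]] = []
        for kind, node in self.nodes:
            if kind == "conv":
                x = node.forward(x, training)
                if node.skip_tag:
                    taps[node.skip_tag] = x
            elif kind in ("pool", "unpool"):
                x = node.forward(x, training)
            else:  # skip sink
                op, tag = node
                local_c = x.shape[-1]
                x = op.forward(x, taps[tag])
                if training:
                    self._skip_state.append((tag, local_c))
        self._taps = taps if training else None
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over the channel axis)."""
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        probs = nn.softmax(self.forward_logits(x, training=False))
        return probs[0] if squeeze else probs

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate, accumulating parameter gradients; returns dx."""
        skip_grads: dict[str, np.ndarray] = {}
        skip_state = list(self._skip_state)
        dy = dlogits
        for kind, node in reversed(self.nodes):
            if kind == "conv":
                if node.skip_tag and node.skip_tag in skip_grads:
                    dy = dy + skip_grads.pop(node.skip_tag)
                dy = node.backward(dy)
            elif kind in ("pool", "unpool"):
                dy = node.backward(dy)
            else:
                op, tag = node
                _, local_c = skip_state.pop()
                if isinstance(op, nn.Add):
                    dy, dskip = op.backward(dy)
                else:
                    dy, dskip = op.backward(dy, local_c)
                skip_grads[tag] = dskip
        self._taps = None
        return dy

    # ---- persistence ----
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for kind, node in self.nodes:
            if kind != "conv":
                continue
            for p in node.parameters:
                state[p.name] = p.data
            state[f"{node.name}.running_mean"] = node.bn.running_mean
            state[f"{node.name}.running_var"] = node.bn.running_var
        return state

    def save(self, path) -> None:
        meta = dict(
            skip_mode=self.spec.skip_mode,
            width_num=self.spec.width_multiplier.numerator,
            width_den=self.spec.width_multiplier.denominator,
            n_classes=self.spec.n_classes,
        )
        np.savez(path, __meta__=np.array(list(meta.items()), dtype=object),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        from fractions import Fraction

        with np.load(path, allow_pickle=True) as f:
            meta = dict(f["__meta__"].tolist())
            spec = rsnn_spec(
                Fraction(int(meta["width_num"]), int(meta["width_den"])),
                skip_mode=str(meta["skip_mode"]),
                n_classes=int(meta["n_classes"]),
            )
            net = cls(spec, seed=0)
            state = {k: f[k] for k in f.files if k != "__meta__"}
        for kind, node in net.nodes:
            if kind != "conv":
                continue
            for p in node.parameters:
                p.data[...] = state[p.name]
            node.bn.running_mean[...] = state[f"{node.name}.running_mean"]
            node.bn.running_var[...] = state[f"{node.name}.running_var"]
        return net


def build_rsnn(spec: ArchitectureSpec | None = None, seed: int = 0,
               **kwargs) -> SegmentationNetwork:
    """Construct the network (full-width additive-skip variant by default)."""
    if spec is None:
        spec = rsnn_spec()
    return SegmentationNetwork(spec, seed=seed, **kwargs)
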