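"""Loss functions, the Adam optimizer, and the training loop.

Defaults follow the reference training recipe: Adam with learning rate 1e-4,
mini-batch 4, L2 regularization 5e-4 on convolution weights, gradient
clipping at global L2 norm 8, 30 epochs, per-pixel two-class cross-entropy
over all pixels of the batch.  Dice and focal losses are available as the
ablation alternatives.  Training is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .network import SegmentationNetwork

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cross_entropy_loss",
    "dice_loss",
    "focal_loss",
    "Adam",
    "train",
    "predict_mask",
]

_EPS = 1e-7


def _check_batch(y: np.ndarray, h: np.ndarray):
    y = np.asarray(y, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty batch")
    if y.shape != h.shape:
        raise ValueError("targets and predictions must have the same shape")
    return y, np.clip(h, _EPS, 1.0 - _EPS)


def cross_entropy_loss(y: np.ndarray, h: np.ndarray) -> float:
    """Mean binary cross-entropy -[y ln h + (1-y) ln(1-h)] over the batch.

    ``y`` are {0,1} targets, ``h`` the predicted foreground probabilities
    (clamped to [eps, 1-eps], eps=1e-7); natural logarithm.
    """
    y, h = _check_batch(y, h)
    return float(-(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)).mean())


def dice_loss(y: np.ndarray, h: np.ndarray, smooth: float = _EPS) -> float:
    """Soft-Dice loss 1 - 2|P.G| / (|P| + |G|), smoothed for empty masks."""
    y, h = _check_batch(y, h)
    inter = (y * h).sum()
    return float(1.0 - (2.0 * inter + smooth) / (y.sum() + h.sum() + smooth))


def focal_loss(y: np.ndarray, h: np.ndarray,
               gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Mean focal loss -alpha (1-p_t)^gamma ln p_t with p_t the target-class
    probability; reduces to alpha-weighted cross-entropy at gamma=0."""
    y, h = _check_batch(y, h)
    pt = np.where(y == 1, h, 1.0 - h)
    return float((-alpha * (1.0 - pt) ** gamma * np.log(pt)).mean())


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    l2_regularization: float = 5e-4
    gradient_threshold: float = 8.0
    #: "global-l2norm" clips the concatenated gradient vector; "element"
    #: clips each component to [-threshold, threshold]
    clip_mode: str = "global-l2norm"
    epochs: int = 30
    seed: int = 0
    loss: str = "cross_entropy"  # cross_entropy | dice | focal
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    #: optional per-class weights (background, nucleus); None = unweighted,
    #: matching the reference setup
    class_weights: tuple[float, float] | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.learning_rate, self.gradient_threshold) <= 0:
            raise ValueError("learning_rate and gradient_threshold must be > 0")
        if self.loss not in ("cross_entropy", "dice", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainHistory:
    """Per-epoch mean loss and pixel accuracy, serializable to CSV."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss", "accuracy"])
            for i, (l, a) in enumerate(zip(self.loss, self.accuracy), start=1):
                writer.writerow([i, f"{l:.6f}", f"{a:.6f}"])

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        epochs = range(1, len(self.loss) + 1)
        ax1.plot(epochs, self.loss); ax1.set_xlabel("epoch"); ax1.set_ylabel("loss")
        ax2.plot(epochs, self.accuracy); ax2.set_xlabel("epoch")
        ax2.set_ylabel("pixel accuracy")
        fig.tight_layout(); fig.savefig(path, dpi=100); plt.close(fig)


class Adam:
    """Adam with decoupled-from-nothing classic L2 (added to the gradient of
    weight tensors) and gradient clipping applied before the moment update."""

    def __init__(self, params: list[nn.Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 l2: float = 0.0, gradient_threshold: float = np.inf,
                 clip_mode: str = "global-l2norm"):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.threshold = gradient_threshold
        self.clip_mode = clip_mode
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        if self.l2:
            for p in self.params:
                if p.is_weight:
                    p.grad += (self.l2 * p.data).astype(p.grad.dtype)
        if np.isfinite(self.threshold):
            if self.clip_mode == "global-l2norm":
                sq = sum(float(np.vdot(p.grad, p.grad)) for p in self.params)
                norm = np.sqrt(sq)
                if norm > self.threshold:
                    scale = self.threshold / norm
                    for p in self.params:
                        p.grad *= scale
            else:
                for p in self.params:
                    np.clip(p.grad, -self.threshold, self.threshold, out=p.grad)
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (np.square(p.grad) - v)
            p.data -= (self.lr * (m / bc1)
                       / (np.sqrt(v / bc2) + self.eps)).astype(p.data.dtype)


def _loss_and_grad(logits: np.ndarray, targets: np.ndarray,
                   config: TrainConfig) -> tuple[float, np.ndarray]:
    """Loss value and d(loss)/d(logits) for the configured loss."""
    if config.loss == "cross_entropy" and config.class_weights is None:
        return nn.softmax_cross_entropy(logits, targets)
    p = nn.softmax(logits)
    h = p[..., 1]
    y = (targets == 1)
    m = targets.size
    yf = y.astype(np.float64)
    hc = np.clip(h.astype(np.float64), _EPS, 1 - _EPS)
    if config.loss == "cross_entropy":
        w0, w1 = config.class_weights
        wmap = np.where(y, w1, w0)
        loss = float((-wmap * (yf * np.log(hc) + (1 - yf) * np.log(1 - hc))).mean())
        dh = wmap * (hc - yf) / (hc * (1 - hc)) / m
    elif config.loss == "dice":
        inter = float((yf * hc).sum()); denom = float(yf.sum() + hc.sum()) + _EPS
        loss = 1.0 - (2 * inter + _EPS) / denom
        dh = (-2 * yf / denom + (2 * inter + _EPS) / denom ** 2)
    else:  # focal
        g, a = config.focal_gamma, config.focal_alpha
        pt = np.where(y, hc, 1 - hc)
        loss = float((-a * (1 - pt) ** g * np.log(pt)).mean())
        dldpt = a * (g * (1 - pt) ** (g - 1) * np.log(pt) - (1 - pt) ** g / pt) / m
        dh = np.where(y, dldpt, -dldpt)
    # chain through the 2-class softmax: h = p1, dlogits = dh * dp1/dlogits
    jac = (h * (1 - h)).astype(np.float64)
    dlogit1 = dh * jac
    dlogits = np.stack([-dlogit1, dlogit1], axis=-1).astype(logits.dtype)
    return loss, dlogits


def train(network: SegmentationNetwork,
          images: np.ndarray, masks: np.ndarray,
          config: TrainConfig | None = None,
          progress: bool = False) -> TrainHistory:
    """Train on a stack of (image, binary mask) pairs.

    ``images``: (N, H, W, 3) uint8 or float in [0,255]; ``masks``: (N, H, W)
    {0,1}.  Inputs are scaled to [0,1] before entering the network.  Returns
    the per-epoch loss/accuracy history; raises on NaN loss.
    """
    config = config or TrainConfig()
    n = len(images)
    if n == 0:
        raise ValueError("empty dataset")
    x_all = np.ascontiguousarray(images, dtype=network.dtype) / 255.0
    t_all = np.ascontiguousarray(masks).astype(np.int64)
    opt = Adam(network.parameters, lr=config.learning_rate,
               l2=config.l2_regularization,
               gradient_threshold=config.gradient_threshold,
               clip_mode=config.clip_mode)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        ep_pixels = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb = x_all[idx], t_all[idx]
            logits = network.forward_logits(xb, training=True)
            loss, dlogits = _loss_and_grad(logits, tb, config)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}; "
                    "lower the learning rate or check the inputs")
            network.zero_grad()
            network.backward(dlogits)
            opt.step()
            ep_loss += loss * tb.size
            ep_correct += int((logits.argmax(-1) == tb).sum())
            ep_pixels += tb.size
        history.loss.append(ep_loss / ep_pixels)
        history.accuracy.append(ep_correct / ep_pixels)
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs} "
                  f"loss {history.loss[-1]:.4f} acc {history.accuracy[-1]:.4f}")
    return history


def predict_mask(network: SegmentationNetwork, image: np.ndarray) -> np.ndarray:
    """Binary nucleus mask by per-pixel argmax; exact 0.5/0.5 ties resolve to
    background (argmax returns the lower index, class 0)."""
    img = np.ascontiguousarray(image, dtype=network.dtype) / 255.0
    probs = network.forward(img)
    return (probs[..., 1] > probs[..., 0]).astype(np.uint8)
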