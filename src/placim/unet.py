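"""U-net placenta segmentation.

A contracting path (double 3x3 convolution + 2x2 max-pool per stage,
channels doubling) meets an expansive path (nearest-neighbour x2
upsampling + convolution, channels halving) through skip connections that
concatenate each encoder stage's feature map into the matching decoder
stage. Convolutions are same-padded so the probability map has exactly
the input's shape, and the input side must be divisible by ``2**depth``.

Training minimises the average of binary cross-entropy and Dice loss on
the foreground-probability map — the Dice term keeps the small-foreground
placenta from being swamped by background pixels. Inference thresholds
the sigmoid probability at 0.5 (ties count as foreground) and by default
keeps only the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _nn
from ._nn import functional as F
from ._nn.checkpoint import load_checkpoint, save_checkpoint


@dataclass(frozen=True)
class UnetSpec:
    depth: int = 2
    base_channels: int = 8
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if min(self.base_channels, self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")

    def to_dict(self) -> dict:
        return {"depth": self.depth, "base_channels": self.base_channels,
                "in_channels": self.in_channels, "out_channels": self.out_channels}


@dataclass(frozen=True)
class SegTrainConfig:
    """Training settings; the defaults are the reference settings
    (batch 8, learning rate 0.001, 200 epochs, plain SGD)."""

    batch_size: int = 8
    learning_rate: float = 0.001
    epochs: int = 200
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


class _DoubleConv(_nn.Module):
    def __init__(self, cin, cout, rng):
        self.c1 = _nn.Conv2d(cin, cout, 3, rng)
        self.r1 = _nn.ReLU()
        self.c2 = _nn.Conv2d(cout, cout, 3, rng)
        self.r2 = _nn.ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class Unet(_nn.Module):
    def __init__(self, spec: UnetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        ch = [spec.base_channels * 2**i for i in range(spec.depth + 1)]
        self.enc = [_DoubleConv(spec.in_channels if i == 0 else ch[i - 1], ch[i], rng)
                    for i in range(spec.depth)]
        self.pools = [_nn.MaxPool2() for _ in range(spec.depth)]
        self.bottleneck = _DoubleConv(ch[spec.depth - 1], ch[spec.depth], rng)
        self.ups = [_nn.Upsample2() for _ in range(spec.depth)]
        # channel-halving conv after each upsample, then the skip concat
        self.upconvs = [_nn.Conv2d(ch[i + 1], ch[i], 3, rng) for i in range(spec.depth)]
        self.dec = [_DoubleConv(2 * ch[i], ch[i], rng) for i in range(spec.depth)]
        self.final = _nn.Conv2d(ch[0], spec.out_channels, 1, rng)

    def _check_size(self, x):
        h, w = x.shape[2], x.shape[3]
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^depth = {div}")

    def forward(self, x):
        """Logit map of the same spatial shape as the input."""
        self._check_size(x)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for i in reversed(range(self.spec.depth)):
            x = self.upconvs[i].forward(self.ups[i].forward(x))
            skip = skips[i]
            self._skip_ch.append(skip.shape[1])
            x = self.dec[i].forward(np.concatenate([skip, x], axis=1))
        return self.final.forward(x)

    def backward(self, dlogits):
        dx = self.final.backward(dlogits)
        dskips = []
        for i in range(self.spec.depth):
            d = self.dec[i].backward(dx)
            ch = self._skip_ch[self.spec.depth - 1 - i]
            dskips.append(d[:, :ch])
            dx = self.ups[i].backward(self.upconvs[i].backward(d[:, ch:]))
        dx = self.bottleneck.backward(dx)
        for i in reversed(range(self.spec.depth)):
            d = self.pools[i].backward(dx)
            d = d + dskips[i]
            dx = self.enc[i].backward(d)
        return dx

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map of a single 2D image."""
        x = _normalize(np.asarray(image, dtype=np.float32))[None, None]
        self.set_training(False)
        logits = self.forward(x)
        return F.sigmoid(logits[0, 0])


def build_unet(spec: UnetSpec, seed: int = 0) -> Unet:
    return Unet(spec, seed=seed)


def _normalize(img: np.ndarray) -> np.ndarray:
    """Per-image z-normalisation; MR intensity scales are arbitrary."""
    return ((img - img.mean()) / (img.std() + 1e-6)).astype(np.float32)


def _stack(records):
    imgs = np.stack([_normalize(np.asarray(r.image, dtype=np.float32))
                     for r in records])[:, None]
    masks = np.stack([np.asarray(r.mask, dtype=np.float32) for r in records])[:, None]
    return imgs, masks


def train_segmenter(records, spec: UnetSpec, cfg: SegTrainConfig,
                    model: Unet | None = None):
    """Train a U-net on (image, mask) records; returns (model, loss_history).

    ``loss_history`` has one mean-batch-loss entry per epoch.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 training records")
    if any(r.mask is None for r in records):
        raise ValueError("every training record needs a mask")
    imgs, masks = _stack(records)
    model = model or build_unet(spec, seed=cfg.seed)
    model.set_training(True)
    opt = _nn.SGD(model.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    n = len(records)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(imgs[idx])
            loss, dlogits = F.dice_bce_loss(logits, masks[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def segment(model: Unet, image: np.ndarray, largest_component: bool = True) -> np.ndarray:
    """Binary placenta mask: probability >= 0.5 is foreground."""
    prob = model.predict_proba(image)
    mask = (prob >= 0.5).astype(np.uint8)
    if largest_component and mask.any():
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            mask = (lab == int(np.argmax(sizes)) + 1).astype(np.uint8)
    return mask


def save_segmenter(path, model: Unet) -> None:
    save_checkpoint(path, {"kind": "unet", "spec": model.spec.to_dict()}, model)


def load_segmenter(path) -> Unet:
    header, arrays = load_checkpoint(path)
    if header.get("kind") != "unet":
        raise ValueError(f"not a U-net checkpoint: {path}")
    model = Unet(UnetSpec(**header["spec"]))
    model.load_state_arrays(arrays)
    return model
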