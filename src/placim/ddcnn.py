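"""Deep dynamic-convolution codec (DDCNN) for unsupervised deep features.

An autoencoder whose convolutions are *dynamic*: each layer carries N
candidate kernels and a lightweight squeeze-and-excitation attention
(global average pool -> FC -> ReLU -> FC -> softmax) that maps the input
feature map to weights w_1..w_N with sum 1; the layer convolves with the
weighted superposition ``sum_i w_i * conv_i``. The encoder applies
``stages`` Group-A blocks (dynamic conv -> ReLU -> batch-norm -> max-pool,
halving the spatial size each stage), then global average pooling and a
linear map to the 100-dimensional deep-feature vector. The decoder
mirrors it with Group-B blocks (nearest-neighbour x2 upsample -> dynamic
conv -> ReLU -> batch-norm) and a final sigmoid so the reconstruction
lives in the input's [0, 1] intensity range.

Training minimises mean squared reconstruction error on ROI bounding-box
crops; afterwards the decoder is discarded and the frozen encoder maps a
crop to its 100-vector.

The printed block order (ReLU before batch-norm) is kept as the default;
``block_order="bn_relu"`` switches to the conventional order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import functional as F
from ._nn.checkpoint import load_checkpoint, save_checkpoint


@dataclass(frozen=True)
class DynamicConvSpec:
    """Specification of one dynamic convolution layer."""

    n_kernels: int = 4
    kernel_size: int = 3
    in_channels: int = 1
    out_channels: int = 8
    softmax_temperature: float = 1.0

    def __post_init__(self):
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")


def make_dynamic_conv(spec: DynamicConvSpec, seed: int = 0) -> _nn.DynamicConv2d:
    rng = np.random.default_rng(seed)
    return _nn.DynamicConv2d(spec.in_channels, spec.out_channels,
                             spec.kernel_size, spec.n_kernels, rng,
                             temperature=spec.softmax_temperature)


def attention_weights(layer: _nn.DynamicConv2d, x: np.ndarray) -> np.ndarray:
    """Attention weights (N_batch, n_kernels); each row sums to 1."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError("expected a non-empty NCHW feature map")
    return layer.attention(x)


def aggregate_kernels(kernels: np.ndarray, weights: np.ndarray,
                      biases: np.ndarray | None = None):
    """Weighted superposition of candidate kernels (and biases).

    kernels: (N, Cout, Cin, k, k); weights: (N,). Returns (kernel, bias).
    """
    kernels = np.asarray(kernels, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if kernels.shape[0] != weights.shape[0]:
        raise ValueError("one weight per kernel required")
    kernel = np.einsum("k,kocuv->ocuv", weights, kernels)
    if biases is None:
        biases = np.zeros((kernels.shape[0], kernels.shape[1]))
    bias = weights @ np.asarray(biases, dtype=np.float64)
    return kernel, bias


def dynamic_conv(x: np.ndarray, kernels: np.ndarray, weights: np.ndarray,
                 biases: np.ndarray | None = None) -> np.ndarray:
    """Convolve with the aggregated kernel ``sum_i w_i * conv_i``.

    By linearity this equals the weighted sum of the per-kernel
    convolutions; both routes are asserted equal in the tests.
    """
    kernel, bias = aggregate_kernels(kernels, weights, biases)
    y, _ = F.conv2d_forward(np.asarray(x, dtype=np.float32),
                            kernel.astype(np.float32), bias.astype(np.float32))
    return y


@dataclass(frozen=True)
class DdcnnSpec:
    stages: int = 5
    base_channels: int = 8
    max_channels: int = 64
    n_kernels: int = 4
    kernel_size: int = 3
    bottleneck_dim: int = 100
    input_size: int = 128
    softmax_temperature: float = 1.0
    block_order: str = "relu_bn"       # printed order; "bn_relu" = conventional

    def __post_init__(self):
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.input_size % 2**self.stages:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^stages "
                f"= {2**self.stages}")
        if self.block_order not in ("relu_bn", "bn_relu"):
            raise ValueError("block_order must be 'relu_bn' or 'bn_relu'")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, self.max_channels)
                for i in range(self.stages)]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "stages", "base_channels", "max_channels", "n_kernels",
            "kernel_size", "bottleneck_dim", "input_size",
            "softmax_temperature", "block_order")}


class _GroupA(_nn.Module):
    """Encoder block: dynamic conv -> (ReLU/BN per order) -> max-pool."""

    def __init__(self, cin, cout, spec: DdcnnSpec, rng):
        self.conv = _nn.DynamicConv2d(cin, cout, spec.kernel_size, spec.n_kernels,
                                      rng, temperature=spec.softmax_temperature)
        self.relu = _nn.ReLU()
        self.bn = _nn.BatchNorm2d(cout)
        self.pool = _nn.MaxPool2()
        self._relu_first = spec.block_order == "relu_bn"

    def forward(self, x):
        x = self.conv.forward(x)
        if self._relu_first:
            x = self.bn.forward(self.relu.forward(x))
        else:
            x = self.relu.forward(self.bn.forward(x))
        return self.pool.forward(x)

    def backward(self, dy):
        d = self.pool.backward(dy)
        if self._relu_first:
            d = self.relu.backward(self.bn.backward(d))
        else:
            d = self.bn.backward(self.relu.backward(d))
        return self.conv.backward(d)


class _GroupB(_nn.Module):
    """Decoder block: upsample x2 -> dynamic conv -> (ReLU/BN per order)."""

    def __init__(self, cin, cout, spec: DdcnnSpec, rng):
        self.up = _nn.Upsample2()
        self.conv = _nn.DynamicConv2d(cin, cout, spec.kernel_size, spec.n_kernels,
                                      rng, temperature=spec.softmax_temperature)
        self.relu = _nn.ReLU()
        self.bn = _nn.BatchNorm2d(cout)
        self._relu_first = spec.block_order == "relu_bn"

    def forward(self, x):
        x = self.conv.forward(self.up.forward(x))
        if self._relu_first:
            return self.bn.forward(self.relu.forward(x))
        return self.relu.forward(self.bn.forward(x))

    def backward(self, dy):
        if self._relu_first:
            d = self.relu.backward(self.bn.backward(dy))
        else:
            d = self.bn.backward(self.relu.backward(dy))
        return self.up.backward(self.conv.backward(d))


class Ddcnn(_nn.Module):
    """The codec; ``encode`` is the deep-feature path, ``forward`` the full
    reconstruction."""

    def __init__(self, spec: DdcnnSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        ch = spec.channels()
        self.enc_blocks = [_GroupA(1 if i == 0 else ch[i - 1], ch[i], spec, rng)
                           for i in range(spec.stages)]
        self.gap = _nn.GlobalAvgPool()
        self.fc_enc = _nn.Linear(ch[-1], spec.bottleneck_dim, rng)
        self._latent_hw = spec.input_size // 2**spec.stages
        self.fc_dec = _nn.Linear(spec.bottleneck_dim, ch[-1] * self._latent_hw**2, rng)
        dec_ch = list(reversed(ch))
        self.dec_blocks = [_GroupB(dec_ch[i], dec_ch[i + 1] if i + 1 < len(dec_ch) else ch[0],
                                   spec, rng)
                           for i in range(spec.stages)]
        self.final = _nn.Conv2d(ch[0], 1, 1, rng)
        self.out_act = _nn.Sigmoid()

    def _check_input(self, x):
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"expected {self.spec.input_size}x{self.spec.input_size} crops, "
                f"got {x.shape[2]}x{x.shape[3]}")

    def encode(self, x):
        self._check_input(x)
        for blk in self.enc_blocks:
            x = blk.forward(x)
        self._enc_map_shape = x.shape
        return self.fc_enc.forward(self.gap.forward(x))

    def decode(self, z):
        n = z.shape[0]
        ch = self.spec.channels()[-1]
        x = self.fc_dec.forward(z).reshape(n, ch, self._latent_hw, self._latent_hw)
        for blk in self.dec_blocks:
            x = blk.forward(x)
        return self.out_act.forward(self.final.forward(x))

    def forward(self, x):
        return self.decode(self.encode(x))

    def backward(self, dy):
        d = self.final.backward(self.out_act.backward(dy))
        for blk in reversed(self.dec_blocks):
            d = blk.backward(d)
        d = self.fc_dec.backward(d.reshape(d.shape[0], -1))
        d = self.gap.backward(self.fc_enc.backward(d).reshape(
            d.shape[0], self._enc_map_shape[1]))
        for blk in reversed(self.enc_blocks):
            d = blk.backward(d)
        return d


def build_ddcnn(spec: DdcnnSpec, seed: int = 0) -> Ddcnn:
    return Ddcnn(spec, seed=seed)


@dataclass(frozen=True)
class DdcnnTrainConfig:
    batch_size: int = 8
    learning_rate: float = 0.001
    epochs: int = 200
    momentum: float = 0.0
    seed: int = 0


def train_autoencoder(model: Ddcnn, crops, cfg: DdcnnTrainConfig):
    """Train the codec to reconstruct its input crops (MSE).

    Returns (model, loss_history); after training, use ``deep_features``
    with the model — the decoder simply goes unused, and the encoder's
    parameters are only changed by training, never by feature extraction.
    """
    crops = [np.asarray(c, dtype=np.float32) for c in crops]
    if len(crops) < 2:
        raise ValueError("need at least 2 crops")
    x_all = np.stack(crops)[:, None]
    model.set_training(True)
    opt = _nn.SGD(model.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    n = len(crops)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            recon = model.forward(x_all[idx])
            loss, dy = F.mse_loss(recon, x_all[idx])
            model.backward(dy)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def reconstruction_mse(model: Ddcnn, crops) -> float:
    """Mean squared reconstruction error over a crop set (eval mode)."""
    model.set_training(False)
    x = np.stack([np.asarray(c, dtype=np.float32) for c in crops])[:, None]
    recon = model.forward(x)
    return float(np.mean((recon.astype(np.float64) - x.astype(np.float64))**2))


def deep_features(model: Ddcnn, crop: np.ndarray) -> np.ndarray:
    """Frozen-encoder 100-vector of one crop; leaves the model unchanged."""
    model.set_training(False)
    x = np.asarray(crop, dtype=np.float32)[None, None]
    return model.encode(x)[0].astype(np.float64)


def save_ddcnn(path, model: Ddcnn) -> None:
    save_checkpoint(path, {"kind": "ddcnn", "spec": model.spec.to_dict()}, model)


def load_ddcnn(path) -> Ddcnn:
    header, arrays = load_checkpoint(path)
    if header.get("kind") != "ddcnn":
        raise ValueError(f"not a DDCNN checkpoint: {path}")
    model = Ddcnn(DdcnnSpec(**header["spec"]))
    model.load_state_arrays(arrays)
    return model
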