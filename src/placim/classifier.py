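"""Fusion classifier for the four invasion types.

The 100 radiomic and 100 deep features are concatenated into a 200-vector,
z-scored with statistics fitted on the training split only, and mapped
through a multilayer perceptron with layer widths 200 (input), 100, 20
and 4, ReLU between the hidden layers and softmax on the output. The
class probabilities are

    S_i = exp(y_i) / sum_j exp(y_j),   i = 0..3,

computed with max-subtraction; the prediction is the argmax with exact
ties broken toward the lowest class index (0 = no invasion, 1 = accreta,
2 = increta, 3 = percreta). Training minimises cross-entropy with plain
SGD (defaults: batch 8, learning rate 0.001, 200 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import functional as F
from ._nn.checkpoint import load_checkpoint, save_checkpoint

INPUT_DIM = 200
HIDDEN_DIMS = (100, 20)
N_CLASSES = 4


def softmax4(y) -> np.ndarray:
    """Probabilities of 4 logits; stable, sums to 1 within 1e-9."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape[-1] != N_CLASSES:
        raise ValueError(f"expected 4 logits, got shape {y.shape}")
    if not np.isfinite(y).all():
        raise ValueError("logits must be finite")
    return F.softmax(y, axis=-1)


@dataclass
class FusedFeatures:
    """Concatenated radiomic ‖ deep feature matrix for a set of cases."""

    radiomic: np.ndarray     # (n, 100)
    deep: np.ndarray         # (n, 100)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.radiomic = np.atleast_2d(np.asarray(self.radiomic, dtype=np.float64))
        self.deep = np.atleast_2d(np.asarray(self.deep, dtype=np.float64))
        if self.radiomic.shape[1] != 100 or self.deep.shape[1] != 100:
            raise ValueError("radiomic and deep blocks must each have 100 columns")
        if self.radiomic.shape[0] != self.deep.shape[0]:
            raise ValueError("radiomic and deep blocks must have equal row counts")

    @property
    def concatenated(self) -> np.ndarray:
        return np.hstack([self.radiomic, self.deep])


@dataclass
class TypingOutput:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_type: int


@dataclass(frozen=True)
class ClfTrainConfig:
    batch_size: int = 8
    learning_rate: float = 0.001
    epochs: int = 200
    momentum: float = 0.0
    seed: int = 0


class InvasionMlp(_nn.Module):
    """The 200-100-20-4 perceptron with stored input standardisation."""

    def __init__(self, seed: int = 0, input_dim: int = INPUT_DIM):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        dims = (input_dim,) + HIDDEN_DIMS + (N_CLASSES,)
        self.layers = [_nn.Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.relus = [_nn.ReLU() for _ in HIDDEN_DIMS]
        # standardisation parameters; fitted on the training split only
        self.feat_mean = np.zeros(input_dim)
        self.feat_scale = np.ones(input_dim)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.feat_mean) / self.feat_scale

    def forward_logits(self, x_std: np.ndarray) -> np.ndarray:
        x = np.asarray(x_std, dtype=np.float32)
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.relus):
                x = self.relus[i].forward(x)
        return x

    def backward(self, dlogits):
        d = dlogits
        for i in reversed(range(len(self.layers))):
            if i < len(self.relus):
                d = self.relus[i].backward(d)
            d = self.layers[i].backward(d)
        return d


def build_mlp(seed: int = 0, input_dim: int = INPUT_DIM) -> InvasionMlp:
    return InvasionMlp(seed=seed, input_dim=input_dim)


def train_classifier(features: np.ndarray | FusedFeatures, labels,
                     cfg: ClfTrainConfig = ClfTrainConfig(),
                     model: InvasionMlp | None = None):
    """Fit the MLP; returns (model, loss_history).

    Standardisation statistics are computed here, from the training
    features only, and stored inside the model — there is no interface
    for refitting them at prediction time.
    """
    x = features.concatenated if isinstance(features, FusedFeatures) else \
        np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    if y.size and (y.min() < 0 or y.max() >= N_CLASSES):
        raise ValueError("labels must lie in {0,1,2,3}")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = model or build_mlp(seed=cfg.seed, input_dim=x.shape[1])
    if x.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} features, got {x.shape[1]}")
    model.feat_mean = x.mean(axis=0)
    scale = x.std(axis=0)
    model.feat_scale = np.where(scale > 0, scale, 1.0)
    xs = model.standardize(x)
    opt = _nn.SGD(model.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(xs[idx])
            loss, dlogits = F.softmax_xent_loss(logits, y[idx])
            model.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_proba(model: InvasionMlp, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} features, got {x.shape[1]}")
    logits = model.forward_logits(model.standardize(x))
    return F.softmax(logits, axis=1)


def predict(model: InvasionMlp, features: np.ndarray) -> TypingOutput:
    """Typing of a single case; exact ties go to the lowest class index."""
    x = np.asarray(features, dtype=np.float64).reshape(1, -1)
    if x.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} features, got {x.shape[1]}")
    logits = model.forward_logits(model.standardize(x))[0]
    probs = softmax4(logits)
    return TypingOutput(logits=np.asarray(logits, dtype=np.float64),
                        probabilities=probs,
                        predicted_type=int(np.argmax(probs)))


def save_classifier(path, model: InvasionMlp) -> None:
    header = {"kind": "invasion_mlp", "input_dim": model.input_dim,
              "feat_mean": model.feat_mean.tolist(),
              "feat_scale": model.feat_scale.tolist()}
    save_checkpoint(path, header, model)


def load_classifier(path) -> InvasionMlp:
    header, arrays = load_checkpoint(path)
    if header.get("kind") != "invasion_mlp":
        raise ValueError(f"not a classifier checkpoint: {path}")
    model = InvasionMlp(input_dim=header["input_dim"])
    model.load_state_arrays(arrays)
    model.feat_mean = np.asarray(header["feat_mean"])
    model.feat_scale = np.asarray(header["feat_scale"])
    return model
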