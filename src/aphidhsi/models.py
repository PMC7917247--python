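"""Classifier architectures and training.

Three residual networks, one per analysis view:

* 1-D: ResNet-18 with every spatial operator re-ranked to one dimension,
  consuming a 100-band first-derivative spectrum as a 1-channel signal.
* 2-D: standard ResNet-18 on the synthesized 3-channel RGB frame.
* 3-D: a compact spectral-spatial residual network for reflectance cubes:
  conv(9x3x3, 5 ch) -> BN -> ReLU -> maxpool(3) -> conv(3x1x1, 3 ch) -> BN ->
  ReLU -> maxpool(3) -> residual block (3 ch, 1x1x1 projection shortcut) ->
  residual block (5 ch, parameter-free zero-padded shortcut) -> global average
  pool -> dense -> softmax.

Training is plain SGD (batch 10) with a stepped learning-rate schedule from
0.1 to 0.01, Xavier initialization, and selection of the checkpoint with the
lowest validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class ModelSpec3D:
    """Layer plan of the 3-D spectral-spatial residual network."""

    conv1_channels: int = 5
    conv1_kernel: tuple = (9, 3, 3)
    conv2_channels: int = 3
    conv2_kernel: tuple = (3, 1, 1)
    pool_size: int = 3
    block1_channels: int = 3
    block2_channels: int = 5
    block_kernel: tuple = (3, 3, 3)
    n_classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule: lr steps from ``lr_initial`` down to ``lr_final`` at
    ``lr_step_epoch`` (defaults to half the epoch budget)."""

    batch_size: int = 10
    epochs: int = 200
    lr_initial: float = 0.1
    lr_final: float = 0.01
    lr_step_epoch: int | None = None
    optimizer: str = "sgd"
    init: str = "xavier"
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) <= 0:
            raise ValueError("batch size and epochs must be positive")
        if not 0 < self.lr_final < self.lr_initial:
            raise ValueError("need 0 < lr_final < lr_initial")

    @property
    def step_epoch(self) -> int:
        return self.lr_step_epoch if self.lr_step_epoch is not None else self.epochs // 2

    def lr_at(self, epoch: int) -> float:
        """Learning rate for 1-based ``epoch``."""
        return self.lr_initial if epoch <= self.step_epoch else self.lr_final


class Model:
    """Backbone (ending in global average pooling) plus a dense head."""

    def __init__(self, tag: str, backbone: nn.Sequential, head: nn.Dense,
                 input_shape: tuple, feature_dim: int):
        self.tag = tag
        self.backbone = backbone
        self.head = head
        self.input_shape = tuple(input_shape)   # per-sample, incl. channel axis
        self.feature_dim = feature_dim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(f"sample shape {tuple(x.shape[1:])} does not match "
                             f"model input {self.input_shape}")
        return self.head.forward(self.backbone.forward(x, train), train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backbone.backward(self.head.backward(dlogits))

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.backbone.forward(x, train=False)

    def params(self):
        return self.backbone.params() + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p["value"].size for p in self.params()))


@dataclass
class TrainedModel:
    """A model frozen at its best-validation-loss checkpoint."""

    tag: str
    model: Model
    history: list = field(default_factory=list)
    config: TrainConfig | None = None
    selected_epoch: int = 0

    @property
    def selected_val_loss(self) -> float:
        return self.history[self.selected_epoch - 1]["val_loss"]


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

_RESNET_STAGES = (64, 128, 256, 512)


def build_resnet18(dimensionality: str, input_shape: tuple, n_classes: int = 2,
                   seed: int = 0) -> Model:
    """ResNet-18 stage plan (4 stages x 2 basic blocks, widths 64..512) in
    1-D or 2-D. ``input_shape`` is per-sample: ``(100,)`` or ``(3, 160, 160)``
    (a leading channel axis is implied for bare 1-D spectra)."""
    if dimensionality not in ("1d", "2d"):
        raise ValueError("dimensionality must be '1d' or '2d'")
    nd = 1 if dimensionality == "1d" else 2
    shape = tuple(input_shape)
    if nd == 1 and len(shape) == 1:
        shape = (1,) + shape
    if len(shape) != nd + 1:
        raise ValueError(f"input_shape {input_shape} inconsistent with {dimensionality}")
    in_ch = shape[0]
    rng = np.random.default_rng(seed)
    layers = [
        nn.ConvNd(in_ch, 64, 7, stride=2, padding=3, nd=nd, rng=rng),
        nn.BatchNorm(64),
        nn.ReLU(),
        nn.MaxPoolNd(3, 2, 1, nd=nd),
    ]
    ch = 64
    for stage, width in enumerate(_RESNET_STAGES):
        for block in range(2):
            stride = 2 if (stage > 0 and block == 0) else 1
            shortcut = "conv" if (stride != 1 or ch != width) else "identity"
            layers.append(nn.ResidualBlock(ch, width, nd=nd, rng=rng, kernel=3,
                                           stride=stride, shortcut=shortcut))
            ch = width
    layers.append(nn.GlobalAvgPool())
    backbone = nn.Sequential(layers)
    head = nn.Dense(ch, n_classes, rng)
    return Model(dimensionality, backbone, head, shape, ch)


def build_cnn3d(spec: ModelSpec3D = ModelSpec3D(),
                input_shape: tuple = (100, 160, 160), seed: int = 0) -> Model:
    """The compact 3-D spectral-spatial residual network (see module docs).

    ``input_shape`` is (bands, H, W); a 1-channel axis is added internally.
    The architecture is shape-flexible: any input with at least 9 bands and
    3 pixels per spatial axis is accepted.
    """
    bands, h, w = input_shape
    if bands < spec.conv1_kernel[0] or h < spec.conv1_kernel[1] or w < spec.conv1_kernel[2]:
        raise ValueError(f"input {input_shape} smaller than the first kernel "
                         f"{spec.conv1_kernel}")
    rng = np.random.default_rng(seed)
    k1, k2 = spec.conv1_kernel, spec.conv2_kernel
    layers = [
        nn.ConvNd(1, spec.conv1_channels, k1, stride=1,
                  padding=tuple(k // 2 for k in k1), nd=3, rng=rng),
        nn.BatchNorm(spec.conv1_channels),
        nn.ReLU(),
        nn.MaxPoolNd(spec.pool_size, 2, 1, nd=3),
        nn.ConvNd(spec.conv1_channels, spec.conv2_channels, k2, stride=1,
                  padding=tuple(k // 2 for k in k2), nd=3, rng=rng),
        nn.BatchNorm(spec.conv2_channels),
        nn.ReLU(),
        nn.MaxPoolNd(spec.pool_size, 2, 1, nd=3),
        nn.ResidualBlock(spec.conv2_channels, spec.block1_channels, nd=3,
                         rng=rng, kernel=spec.block_kernel, shortcut="conv"),
        nn.ResidualBlock(spec.block1_channels, spec.block2_channels, nd=3,
                         rng=rng, kernel=spec.block_kernel, shortcut="pad"),
        nn.GlobalAvgPool(),
    ]
    backbone = nn.Sequential(layers)
    head = nn.Dense(spec.block2_channels, spec.n_classes, rng)
    return Model("3d", backbone, head, (1,) + tuple(input_shape),
                 spec.block2_channels)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _batched_logits(model: Model, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.forward(X[i:i + batch_size], train=False))
    return np.concatenate(out, axis=0)


def train_model(model: Model, train: tuple, validation: tuple,
                config: TrainConfig) -> TrainedModel:
    """SGD training with per-epoch logging and best-validation selection.

    ``train`` and ``validation`` are ``(X, y)`` pairs with X shaped
    ``(n,) + model.input_shape`` and binary integer labels. Deterministic for
    a fixed ``config.seed``. Raises ``RuntimeError`` on NaN loss.
    """
    Xtr, ytr = np.asarray(train[0]), np.asarray(train[1])
    Xval, yval = np.asarray(validation[0]), np.asarray(validation[1])
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    history = []
    best = (np.inf, None, 0)
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Xtr[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss}) at epoch {epoch}")
            model.backward(dlogits)
            for p in model.params():
                p["value"] -= lr * p["grad"]
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
        val_logits = _batched_logits(model, Xval, config.batch_size)
        val_loss, _ = nn.cross_entropy(val_logits, yval)
        val_acc = float((val_logits.argmax(axis=1) == yval).mean())
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": float(np.mean(losses)),
                        "train_acc": correct / len(Xtr),
                        "val_loss": float(val_loss), "val_acc": val_acc})
        if val_loss < best[0]:
            state = nn.get_state(model.backbone) + nn.get_state(model.head)
            best = (float(val_loss), state, epoch)
    n_backbone = len(nn.get_state(model.backbone))
    nn.set_state(model.backbone, best[1][:n_backbone])
    nn.set_state(model.head, best[1][n_backbone:])
    return TrainedModel(tag=model.tag, model=model, history=history,
                        config=config, selected_epoch=best[2])


def predict(model: Model | TrainedModel, samples: np.ndarray,
            batch_size: int = 32):
    """Labels and pre-softmax class scores (scores kept for saliency)."""
    net = model.model if isinstance(model, TrainedModel) else model
    X = np.asarray(samples)
    single = X.shape == net.input_shape
    if single:
        X = X[None]
    scores = _batched_logits(net, X, batch_size)
    labels = scores.argmax(axis=1)
    if single:
        return int(labels[0]), scores[0]
    return labels, scores


def extract_pooled_features(model: TrainedModel, samples: np.ndarray,
                            batch_size: int = 32) -> np.ndarray:
    """Global-average-pooling features of a *trained* model, one row per
    sample (512 for the ResNet-18 variants, 5 for the 3-D network)."""
    if not isinstance(model, TrainedModel):
        raise TypeError("feature extraction requires a TrainedModel "
                        "(train the network first)")
    X = np.asarray(samples)
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.model.features(X[i:i + batch_size]))
    return np.concatenate(out, axis=0)
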