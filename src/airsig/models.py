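"""Seven time-series classifiers and their training harness.

All architectures consume batches shaped (batch, input_length, n_channels)
and produce class probabilities over the enrolled subjects.  Default layer
parameters follow the published layer descriptions:

* FCN — 3 conv stages, kernels (8, 5, 3), filters (128, 256, 128), batch
  norm + ReLU each, global average pooling, softmax head.
* MLP — 3 hidden layers of 732 units on the flattened input.
* Time-CNN — 2 conv stages of kernel 7 with 6 and 12 filters, each followed
  by average pooling (kernel 3, stride 3), flatten, softmax.
* MC-DCNN — one branch per channel: 2 x (conv kernel 5, 8 filters, ReLU,
  max pool 2/2); branch outputs concatenated into a 732-unit hidden layer.
* Encoder — 3 conv stages, kernels (5, 11, 21), filters (128, 256, 512),
  valid padding, instance norm + PReLU + dropout, max pool 2/2 after the
  first two stages, then a time-softmax attention head.
* ResNet — 3 residual blocks of 3 convs (kernels 8, 5, 3), filters doubling
  64 -> 128 -> 256, global average pooling.
* InceptionTime — 2 blocks x 3 inception modules (bottleneck 1x1, parallel
  convs with kernels 3/5/8/11/17 plus a max-pool branch), residual
  connections input -> block 1 and block 1 -> block 2, global average
  pooling + fully connected head.  A single network per run (no ensemble).

The training defaults mirror the published hyper-parameter table behind the
``paper_defaults`` flag (learning rate 1e-5, 1500 epochs; Adam everywhere
except Adadelta for MLP and SGD for MC-DCNN).  Desk defaults use the same
optimizer per architecture with practical learning rates and 100 epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from airsig.errors import ConfigError, TrainingDivergedError, TrainingError
from airsig.nn import (
    SGD,
    Adadelta,
    Adam,
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool,
    InstanceNorm1d,
    MaxPool1d,
    Module,
    PReLU,
    ReLU,
    Sequential,
    TimeSoftmaxAttention,
    softmax,
    softmax_cross_entropy,
)
from airsig.preprocess import dataset_to_arrays
from airsig.schema import SignatureDataset

ARCHITECTURES = ("FCN", "MLP", "ResNet", "Encoder", "MCDCNN", "TimeCNN", "InceptionTime")

#: optimizer per architecture from the published hyper-parameter table
PAPER_OPTIMIZER = {
    "FCN": "adam", "MLP": "adadelta", "ResNet": "adam", "Encoder": "adam",
    "MCDCNN": "sgd", "TimeCNN": "adam", "InceptionTime": "adam",
}
PAPER_LEARNING_RATE = 1e-5
PAPER_EPOCHS = 1500

_DESK_LR = {"adam": 1e-3, "adadelta": 1.0, "sgd": 0.01}


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    input_length: int
    n_channels: int
    n_classes: int
    #: architecture-parameter overrides (e.g. {"filters": (16, 32, 16)})
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if not 1 <= self.n_channels <= 9:
            raise ConfigError(f"n_channels must be in 1..9, got {self.n_channels}")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.input_length < 2:
            raise ConfigError(f"input_length must be >= 2, got {self.input_length}")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: Optional[str] = None          # default: per-architecture table
    learning_rate: Optional[float] = None    # default: desk rate for the optimizer
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    normalize: bool = True                   # z-score per channel with train statistics
    paper_defaults: bool = False

    def resolve(self, architecture: str) -> tuple[str, float, int]:
        opt = self.optimizer or PAPER_OPTIMIZER[architecture]
        if self.paper_defaults:
            lr = self.learning_rate if self.learning_rate is not None else PAPER_LEARNING_RATE
            epochs = PAPER_EPOCHS if self.epochs == 100 else self.epochs
            return opt, lr, epochs
        lr = self.learning_rate if self.learning_rate is not None else _DESK_LR[opt]
        return opt, lr, self.epochs


@dataclass
class TrainResult:
    train_loss: list[float]
    val_loss: list[float]
    train_acc: float
    val_acc: float
    spec: ModelSpec
    config: TrainConfig
    normalization: Optional[tuple[np.ndarray, np.ndarray]] = None


# ---------------------------------------------------------------------------
# composite modules

class ResidualBlock(Module):
    """conv(8)-BN-ReLU, conv(5)-BN-ReLU, conv(3)-BN, plus shortcut, then ReLU."""

    def __init__(self, in_channels: int, filters: int, kernels=(8, 5, 3), rng=None):
        self.branch = Sequential(
            Conv1d(in_channels, filters, kernels[0], rng=rng, name="res-conv1"),
            BatchNorm1d(filters), ReLU(),
            Conv1d(filters, filters, kernels[1], rng=rng, name="res-conv2"),
            BatchNorm1d(filters), ReLU(),
            Conv1d(filters, filters, kernels[2], rng=rng, name="res-conv3"),
            BatchNorm1d(filters),
        )
        if in_channels != filters:
            self.shortcut: Optional[Sequential] = Sequential(
                Conv1d(in_channels, filters, 1, rng=rng, name="res-shortcut"),
                BatchNorm1d(filters),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()
        self.filters = filters

    def forward(self, x, training=False):
        main = self.branch.forward(x, training=training)
        short = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        return self.relu.forward(main + short, training=training)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        g_main = self.branch.backward(grad)
        g_short = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_main + g_short


class InceptionModule(Module):
    """Bottleneck + 5 parallel convs (kernels 3/5/8/11/17) + max-pool branch,
    concatenated, batch-normalized, rectified."""

    def __init__(self, in_channels: int, n_filters: int = 32, bottleneck: int = 32,
                 kernels: Sequence[int] = (3, 5, 8, 11, 17), rng=None):
        self.use_bottleneck = in_channels > 1
        branch_in = bottleneck if self.use_bottleneck else in_channels
        self.bottleneck = (
            Conv1d(in_channels, bottleneck, 1, bias=False, rng=rng, name="inc-bottleneck")
            if self.use_bottleneck else None
        )
        self.branch_convs = [
            Conv1d(branch_in, n_filters, k, bias=False, rng=rng, name=f"inc-conv{k}")
            for k in kernels
        ]
        self.pool = MaxPool1d(3, 1, padding="same", name="inc-pool")
        self.pool_conv = Conv1d(in_channels, n_filters, 1, bias=False, rng=rng, name="inc-poolconv")
        self.bn = BatchNorm1d(n_filters * (len(kernels) + 1))
        self.relu = ReLU()
        self.n_filters = n_filters
        self.out_channels = n_filters * (len(kernels) + 1)

    def forward(self, x, training=False):
        b = self.bottleneck.forward(x, training=training) if self.use_bottleneck else x
        outs = [conv.forward(b, training=training) for conv in self.branch_convs]
        outs.append(self.pool_conv.forward(self.pool.forward(x, training=training),
                                           training=training))
        y = np.concatenate(outs, axis=2)
        return self.relu.forward(self.bn.forward(y, training=training), training=training)

    def backward(self, grad):
        grad = self.bn.backward(self.relu.backward(grad))
        nf = self.n_filters
        g_b = None
        for i, conv in enumerate(self.branch_convs):
            g = conv.backward(grad[:, :, i * nf:(i + 1) * nf])
            g_b = g if g_b is None else g_b + g
        g_pool = self.pool.backward(
            self.pool_conv.backward(grad[:, :, len(self.branch_convs) * nf:])
        )
        g_in = self.bottleneck.backward(g_b) if self.use_bottleneck else g_b
        return g_in + g_pool


class InceptionBody(Module):
    """Two blocks of three inception modules with residual connections
    input -> block 1 and block 1 -> block 2."""

    def __init__(self, in_channels: int, n_filters: int = 32, bottleneck: int = 32,
                 kernels: Sequence[int] = (3, 5, 8, 11, 17), rng=None):
        def block(c_in):
            mods = []
            for _ in range(3):
                mod = InceptionModule(c_in, n_filters, bottleneck, kernels, rng=rng)
                mods.append(mod)
                c_in = mod.out_channels
            return mods, c_in

        self.block1, width = block(in_channels)
        self.short1 = Sequential(
            Conv1d(in_channels, width, 1, bias=False, rng=rng, name="inc-short1"),
            BatchNorm1d(width),
        )
        self.relu1 = ReLU()
        self.block2, width = block(width)
        self.short2 = Sequential(
            Conv1d(width, width, 1, bias=False, rng=rng, name="inc-short2"),
            BatchNorm1d(width),
        )
        self.relu2 = ReLU()
        self.out_channels = width

    def forward(self, x, training=False):
        h = x
        for mod in self.block1:
            h = mod.forward(h, training=training)
        z1 = self.relu1.forward(h + self.short1.forward(x, training=training), training=training)
        h2 = z1
        for mod in self.block2:
            h2 = mod.forward(h2, training=training)
        return self.relu2.forward(h2 + self.short2.forward(z1, training=training),
                                  training=training)

    def backward(self, grad):
        grad = self.relu2.backward(grad)
        g_main = grad
        for mod in reversed(self.block2):
            g_main = mod.backward(g_main)
        g_z1 = g_main + self.short2.backward(grad)
        g_z1 = self.relu1.backward(g_z1)
        g_b1 = g_z1
        for mod in reversed(self.block1):
            g_b1 = mod.backward(g_b1)
        return g_b1 + self.short1.backward(g_z1)


class GAPNet(Module):
    """body -> global average pooling -> linear head.  Caches the last
    convolutional feature maps so class activation maps can be formed."""

    def __init__(self, body: Module, head: Dense):
        self.body = body
        self.gap = GlobalAvgPool()
        self.head = head
        self.features_: Optional[np.ndarray] = None

    def forward(self, x, training=False):
        feats = self.body.forward(x, training=training)
        self.features_ = feats
        return self.head.forward(self.gap.forward(feats, training=training), training=training)

    def backward(self, grad):
        return self.body.backward(self.gap.backward(self.head.backward(grad)))


class MCDCNNNet(Module):
    """One independent convolutional branch per input channel, concatenated."""

    def __init__(self, spec: ModelSpec, rng=None):
        p = spec.params
        kernel = p.get("kernel", 5)
        filters = p.get("filters", 8)
        hidden = p.get("hidden_units", 732)
        self.branches = []
        for i in range(spec.n_channels):
            self.branches.append(Sequential(
                Conv1d(1, filters, kernel, rng=rng, name=f"mcdcnn-b{i}-conv1"), ReLU(),
                MaxPool1d(2, 2, name=f"mcdcnn-b{i}-pool1"),
                Conv1d(filters, filters, kernel, rng=rng, name=f"mcdcnn-b{i}-conv2"), ReLU(),
                MaxPool1d(2, 2, name=f"mcdcnn-b{i}-pool2"),
                Flatten(),
            ))
        branch_out = (spec.input_length // 2 // 2) * filters
        self.hidden = Dense(branch_out * spec.n_channels, hidden, rng=rng)
        self.hidden_relu = ReLU()
        self.head = Dense(hidden, spec.n_classes, rng=rng)
        self._branch_out = branch_out

    def forward(self, x, training=False):
        outs = [
            branch.forward(x[:, :, i:i + 1], training=training)
            for i, branch in enumerate(self.branches)
        ]
        h = np.concatenate(outs, axis=1)
        h = self.hidden_relu.forward(self.hidden.forward(h, training=training), training=training)
        return self.head.forward(h, training=training)

    def backward(self, grad):
        g = self.hidden.backward(self.hidden_relu.backward(self.head.backward(grad)))
        w = self._branch_out
        pieces = []
        for i, branch in enumerate(self.branches):
            pieces.append(branch.backward(g[:, i * w:(i + 1) * w]))
        return np.concatenate(pieces, axis=2)


# ---------------------------------------------------------------------------
# builders

def build_model(spec: ModelSpec, seed: int = 0) -> Module:
    """Instantiate an untrained network for `spec` with seeded initialization."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    p = spec.params
    c, length, k_cls = spec.n_channels, spec.input_length, spec.n_classes

    if spec.architecture == "FCN":
        kernels = p.get("kernels", (8, 5, 3))
        filters = p.get("filters", (128, 256, 128))
        layers, c_in = [], c
        for ker, f in zip(kernels, filters):
            layers += [Conv1d(c_in, f, ker, rng=rng, name=f"fcn-conv{ker}"),
                       BatchNorm1d(f), ReLU()]
            c_in = f
        return GAPNet(Sequential(*layers), Dense(c_in, k_cls, rng=rng))

    if spec.architecture == "MLP":
        hidden = p.get("hidden_units", (732, 732, 732))
        mods: list[Module] = [Flatten()]
        w_in = length * c
        for h in hidden:
            mods += [Dense(w_in, h, rng=rng), ReLU()]
            w_in = h
        mods.append(Dense(w_in, k_cls, rng=rng))
        return Sequential(*mods)

    if spec.architecture == "TimeCNN":
        filters = p.get("filters", (6, 12))
        kernel = p.get("kernel", 7)
        net = Sequential(
            Conv1d(c, filters[0], kernel, rng=rng, name="timecnn-conv1"), ReLU(),
            AvgPool1d(3, 3, name="timecnn-pool1"),
            Conv1d(filters[0], filters[1], kernel, rng=rng, name="timecnn-conv2"), ReLU(),
            AvgPool1d(3, 3, name="timecnn-pool2"),
            Flatten(),
        )
        flat = (length // 3 // 3) * filters[1]
        if flat < 1:
            raise ConfigError("timecnn-pool2: pooling chain reduced length below 1")
        net.modules.append(Dense(flat, k_cls, rng=rng))
        return net

    if spec.architecture == "MCDCNN":
        if spec.input_length // 4 < 1:
            raise ConfigError("mcdcnn-pool2: pooling chain reduced length below 1")
        return MCDCNNNet(spec, rng=rng)

    if spec.architecture == "Encoder":
        kernels = p.get("kernels", (5, 11, 21))
        filters = p.get("filters", (128, 256, 512))
        dropout = p.get("dropout", 0.2)
        drop_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(18,)))
        mods = []
        c_in = c
        for i, (ker, f) in enumerate(zip(kernels, filters)):
            mods += [
                Conv1d(c_in, f, ker, padding="valid", rng=rng, name=f"encoder-conv{i + 1}"),
                InstanceNorm1d(f), PReLU(f), Dropout(dropout, rng=drop_rng),
            ]
            if i < 2:
                mods.append(MaxPool1d(2, 2, name=f"encoder-pool{i + 1}"))
            c_in = f
        mods.append(TimeSoftmaxAttention())
        mods.append(Dense(filters[-1] // 2, k_cls, rng=rng))
        return Sequential(*mods)

    if spec.architecture == "ResNet":
        kernels = p.get("kernels", (8, 5, 3))
        filters = p.get("filters", (64, 128, 256))
        blocks, c_in = [], c
        for f in filters:
            blocks.append(ResidualBlock(c_in, f, kernels=kernels, rng=rng))
            c_in = f
        return GAPNet(Sequential(*blocks), Dense(c_in, k_cls, rng=rng))

    if spec.architecture == "InceptionTime":
        body = InceptionBody(
            c,
            n_filters=p.get("n_filters", 32),
            bottleneck=p.get("bottleneck", 32),
            kernels=p.get("kernels", (3, 5, 8, 11, 17)),
            rng=rng,
        )
        return GAPNet(body, Dense(body.out_channels, k_cls, rng=rng))

    raise ConfigError(f"unknown architecture {spec.architecture!r}")  # pragma: no cover


def small_params(architecture: str) -> dict:
    """Reduced-width parameters for desk-scale runs of the wide architectures."""
    return {
        "FCN": {"filters": (16, 32, 16)},
        "MLP": {"hidden_units": (64, 64, 64)},
        "ResNet": {"filters": (8, 16, 32)},
        "Encoder": {"filters": (16, 32, 32)},
        "MCDCNN": {"hidden_units": 64},
        "TimeCNN": {},
        "InceptionTime": {"n_filters": 4, "bottleneck": 4},
    }[architecture]


# ---------------------------------------------------------------------------
# training

def _make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "adadelta":
        return Adadelta(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=0.9)
    raise ConfigError(f"unknown optimizer {name!r}")


def _as_arrays(data, input_length: int):
    if isinstance(data, SignatureDataset):
        x, y, _ = dataset_to_arrays(data, input_length)
        return x, y, None
    if len(data) == 2:
        x, y = data
        return np.asarray(x, dtype=np.float64), np.asarray(y), None
    x, y, w = data
    return np.asarray(x, dtype=np.float64), np.asarray(y), np.asarray(w, dtype=np.float64)


def predict_proba(model: Module, x: np.ndarray,
                  normalization: Optional[tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
    if normalization is not None:
        mean, std = normalization
        x = (x - mean) / std
    return softmax(model.forward(x, training=False))


def train_model(
    model: Module,
    train: Union[SignatureDataset, tuple],
    val: Union[SignatureDataset, tuple],
    config: TrainConfig,
    spec: Optional[ModelSpec] = None,
) -> TrainResult:
    """Mini-batch training, deterministic given the config seed.

    `train`/`val` may be :class:`SignatureDataset` or (X, y[, sample_weight])
    tuples.  Sample weights (from missing-record re-weighting) scale each
    record's contribution to the cross-entropy.
    """
    if spec is None and (isinstance(train, SignatureDataset) or isinstance(val, SignatureDataset)):
        raise ConfigError("spec (with input_length) is required when training from datasets")
    input_length = spec.input_length if spec else None
    x_tr, y_tr, w_tr = _as_arrays(train, input_length)
    x_va, y_va, _ = _as_arrays(val, input_length)
    arch = spec.architecture if spec else "FCN"

    missing = set(np.unique(y_va)) - set(np.unique(y_tr))
    if missing:
        raise TrainingError(f"classes {sorted(missing)} present in validation but absent from training")

    normalization = None
    if config.normalize:
        mean = x_tr.mean(axis=(0, 1))
        std = x_tr.std(axis=(0, 1))
        std[std == 0] = 1.0
        normalization = (mean, std)
        x_tr = (x_tr - mean) / std
        x_va = (x_va - mean) / std

    opt_name, lr, epochs = config.resolve(arch)
    params = list(model.parameters())
    optimizer = _make_optimizer(opt_name, params, lr)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(23,)))

    n = x_tr.shape[0]
    train_curve, val_curve = [], []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_tr[idx], training=True)
            weight = None if w_tr is None else w_tr[idx]
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx], sample_weight=weight)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        train_curve.append(epoch_loss / n_batches)
        val_logits = model.forward(x_va, training=False)
        val_loss, _ = softmax_cross_entropy(val_logits, y_va)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        val_curve.append(val_loss)

    train_acc = float(np.mean(model.forward(x_tr, training=False).argmax(axis=1) == y_tr))
    val_acc = float(np.mean(model.forward(x_va, training=False).argmax(axis=1) == y_va))
    return TrainResult(
        train_loss=train_curve, val_loss=val_curve,
        train_acc=train_acc, val_acc=val_acc,
        spec=spec, config=config, normalization=normalization,
    )


# ---------------------------------------------------------------------------
# model-selection experiment design

def plan_model_selection(
    n_devices: int = 2,
    architectures: Sequence[str] = ARCHITECTURES,
    n_channels: int = 9,
) -> list[tuple[str, str, str]]:
    """Enumerate the (device, view, architecture) cells of the selection design:
    one uni-variate view per channel plus the multivariate view."""
    views = [f"channel_{i}" for i in range(n_channels)] + ["multivariate"]
    return [
        (f"device_{d}", view, arch)
        for d in range(n_devices)
        for view in views
        for arch in architectures
    ]


def run_model_selection(
    datasets: dict[str, SignatureDataset],
    config: TrainConfig,
    input_length: int = 100,
    architectures: Sequence[str] = ARCHITECTURES,
    test_fraction: float = 0.2,
    params_fn=small_params,
) -> pd.DataFrame:
    """Train every (device, view, architecture) cell; failed cells are flagged,
    not fatal.  Returns one row per cell with loss/accuracy columns."""
    from airsig.preprocess import Coalition, SplitSpec, extract_coalition, split_dataset

    rows = []
    for device, dataset in datasets.items():
        n_ch = len(dataset.channels)
        views = [(f"channel_{i}", Coalition((i,))) for i in range(n_ch)]
        views.append(("multivariate", Coalition(tuple(range(n_ch)))))
        train_ds, test_ds = split_dataset(
            dataset, SplitSpec(test_fraction=test_fraction, seed=config.seed)
        )
        for view_name, coalition in views:
            tr_view = extract_coalition(train_ds, coalition)
            te_view = extract_coalition(test_ds, coalition)
            for arch in architectures:
                spec = ModelSpec(
                    architecture=arch, input_length=input_length,
                    n_channels=len(coalition), n_classes=dataset.n_subjects,
                    params=params_fn(arch) if params_fn else {},
                )
                row = {"device": device, "view": view_name, "architecture": arch}
                try:
                    model = build_model(spec, seed=config.seed)
                    res = train_model(model, tr_view, te_view, config, spec=spec)
                    row.update(
                        train_loss=res.train_loss[-1], val_loss=res.val_loss[-1],
                        train_acc=res.train_acc, val_acc=res.val_acc, error="",
                    )
                except Exception as exc:  # grid completes; cell flagged
                    row.update(train_loss=np.nan, val_loss=np.nan,
                               train_acc=np.nan, val_acc=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
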