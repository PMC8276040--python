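"""Training, evaluation, prediction and checkpointing for the phenotype CNN."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import PHENOTYPES
from ._nn import Adam, Sequential, softmax, softmax_cross_entropy
from .data import LabeledCellImage, augment, to_arrays
from .model import ModelSpec, build_model


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    dropout: float = 0.5
    epochs: int = 250
    folds: int = 3
    seed: int = 0
    augmentation: str = "dihedral"  # "dihedral", "dihedral-static" or "none"
    target_val_accuracy: float | None = None  # early stop once reached

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, cols = predicted
    classes: tuple[str, ...] = PHENOTYPES

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    @property
    def per_class_recall(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


_DIHEDRAL = [
    lambda a: a,
    lambda a: np.rot90(a, 1, axes=(1, 2)),
    lambda a: np.rot90(a, 2, axes=(1, 2)),
    lambda a: np.rot90(a, 3, axes=(1, 2)),
    lambda a: a[:, :, ::-1],
    lambda a: np.rot90(a, 1, axes=(1, 2))[:, :, ::-1],
    lambda a: np.rot90(a, 2, axes=(1, 2))[:, :, ::-1],
    lambda a: np.rot90(a, 3, axes=(1, 2))[:, :, ::-1],
]


def _forward_batches(network: Sequential, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [network.forward(x[i : i + batch], train=False) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def _eval_loss_acc(network: Sequential, x: np.ndarray, y: np.ndarray):
    logits = _forward_batches(network, x)
    probs = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    network: Sequential,
    train_set: list[LabeledCellImage],
    val_set: list[LabeledCellImage],
    cfg: TrainConfig,
) -> tuple[Sequential, History]:
    """Mini-batch Adam training with per-epoch validation tracking.

    ``augmentation="dihedral"`` applies a random dihedral transform to every
    training batch (stochastic, epoch-budget friendly); ``"dihedral-static"``
    expands the training set eightfold up front, matching the static
    ``augment`` operation; validation data is never augmented.
    """
    if not train_set:
        raise ValueError("empty training set")
    if cfg.augmentation == "dihedral-static":
        train_set = augment(train_set)
    x_tr, y_tr = to_arrays(train_set)
    x_val, y_val = to_arrays(val_set) if val_set else (None, None)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(network.params(), lr=cfg.learning_rate)
    hist = History()
    n = len(x_tr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb = x_tr[sel]
            if cfg.augmentation == "dihedral":
                xb = np.ascontiguousarray(_DIHEDRAL[int(rng.integers(8))](xb))
            logits = network.forward(xb, train=True)
            loss, grad = softmax_cross_entropy(logits, y_tr[sel])
            network.backward(grad)
            opt.step()
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        if x_val is not None and len(x_val):
            vloss, vacc = _eval_loss_acc(network, x_val, y_val)
            hist.val_loss.append(vloss)
            hist.val_accuracy.append(vacc)
            if cfg.target_val_accuracy is not None and vacc >= cfg.target_val_accuracy:
                break
    return network, hist


def cross_validate(
    spec: ModelSpec, pool: list[LabeledCellImage], cfg: TrainConfig
) -> list[History]:
    """K-fold cross-validation; folds are formed at source-cell level before
    any augmentation so augmented variants never straddle a fold boundary."""
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(pool))
    folds = np.array_split(idx, cfg.folds)
    histories = []
    for k in range(cfg.folds):
        val = [pool[i] for i in folds[k]]
        tr = [pool[i] for j, f in enumerate(folds) if j != k for i in f]
        net = build_model(spec, dropout=cfg.dropout, seed=cfg.seed + k)
        _, hist = train(net, tr, val, cfg)
        histories.append(hist)
    return histories


def evaluate(
    network: Sequential, test_set: list[LabeledCellImage]
) -> tuple[float, ConfusionMatrix]:
    if not test_set:
        raise ValueError("empty test set")
    x, y = to_arrays(test_set)
    pred = _forward_batches(network, x).argmax(axis=1)
    k = len(PHENOTYPES)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, pred), 1)
    cm = ConfusionMatrix(counts=counts)
    return cm.accuracy, cm


def predict(
    network: Sequential, cells: list[LabeledCellImage]
) -> tuple[list[str], np.ndarray]:
    """Argmax labels and per-class probability vectors (ties -> class order)."""
    x = np.stack([c.pixels for c in cells]).astype(np.float32)[..., None]
    probs = softmax(_forward_batches(network, x).astype(np.float64))
    labels = [PHENOTYPES[int(i)] for i in probs.argmax(axis=1)]
    return labels, probs


def save_checkpoint(path, network: Sequential, spec: ModelSpec, cfg: TrainConfig) -> None:
    """Weights as .npz plus a JSON sidecar with spec/config/class order."""
    path = Path(path)
    flat = {}
    for i, st in enumerate(network.state()):
        for key, val in st.items():
            flat[f"{i}.{key}"] = val
    np.savez(path.with_suffix(".npz"), **flat)
    sidecar = {
        "model_spec": spec.__dict__,
        "train_config": {k: v for k, v in cfg.__dict__.items()},
        "classes": list(PHENOTYPES),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[Sequential, ModelSpec]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(**sidecar["model_spec"])
    cfg = sidecar["train_config"]
    network = build_model(spec, dropout=cfg.get("dropout", 0.5))
    data = np.load(path.with_suffix(".npz"))
    states: list[dict] = [{} for _ in network.layers]
    for key in data.files:
        i, name = key.split(".", 1)
        states[int(i)][name] = data[key]
    network.load_state(states)
    return network, spec
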