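"""Bifocal convolutional classifier for immunoreactive cell detection.

The model ingests co-centred patch pairs — a narrow 32x32 crop focused on
the candidate cell and a wide 64x64 crop carrying its tissue context —
through two convolutional sub-networks. The two branch feature vectors
are concatenated and passed to a small fully-connected classifier that
emits a two-class probability (cell present / absent).

Default training recipe: SGD with learning rate 0.0005 decaying
gradually (cosine) to 0.00005, momentum 0.9, weight decay 0.005, batch
size 32, 70 epochs. Tests and the synthetic end-to-end workflow use far
fewer epochs; the synthetic task is constructed to be separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve, auc as _auc

from .minicnn import (
    Conv2d, ReLU, MaxPool2, Flatten, Dense, Sequential, SGD,
    softmax, softmax_cross_entropy,
)

NARROW_SIZE = 32
WIDE_SIZE = 64


@dataclass
class BCNNConfig:
    """Architecture and optimisation settings for the bifocal CNN."""

    channels: tuple[int, ...] = (16, 32, 64)
    hidden: int = 128
    learning_rate: float = 0.0005
    lr_min: float = 0.00005
    momentum: float = 0.9
    weight_decay: float = 0.005
    batch_size: int = 32
    epochs: int = 70
    balanced_sampling: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("need at least one conv block per branch")
        # three 2x2 pools bring 32 -> 4; more blocks than pools fit is invalid
        if NARROW_SIZE // (2 ** len(self.channels)) < 1:
            raise ValueError(
                f"{len(self.channels)} conv/pool blocks collapse the 32px branch"
            )
        if not (0 < self.learning_rate and 0 <= self.momentum < 1):
            raise ValueError("invalid optimiser settings")


class BifocalNet:
    """Two conv sub-nets -> feature concatenation -> classifier head."""

    def __init__(self, config: BCNNConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)

        def branch(in_size: int) -> tuple[Sequential, int]:
            layers: list = []
            c_in, size = 3, in_size
            for i, c_out in enumerate(config.channels):
                layers += [Conv2d(c_in, c_out, rng, input_grad=i > 0),
                           ReLU(), MaxPool2()]
                c_in = c_out
                size //= 2
            # flatten (not pool) so the head stays sensitive to where the
            # cell sits in the window — sliding-window localisation needs it
            layers.append(Flatten())
            return Sequential(*layers), size * size * c_in

        self.narrow_net, self._narrow_feat = branch(NARROW_SIZE)
        self.wide_net, wide_feat = branch(WIDE_SIZE)
        self.head = Sequential(
            Dense(self._narrow_feat + wide_feat, config.hidden, rng), ReLU(),
            Dense(config.hidden, 2, rng),
        )

    # -- plumbing ---------------------------------------------------------
    def params(self):
        return self.narrow_net.params() + self.wide_net.params() + self.head.params()

    def forward(self, narrow: np.ndarray, wide: np.ndarray) -> np.ndarray:
        """Logits for a batch of (narrow, wide) pairs in NCHW float32."""
        fa = self.narrow_net.forward(narrow)
        fb = self.wide_net.forward(wide)
        return self.head.forward(np.concatenate([fa, fb], axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        split = self._narrow_feat
        self.narrow_net.backward(dfeat[:, :split])
        self.wide_net.backward(dfeat[:, split:])

    def predict_proba(self, narrow: np.ndarray, wide: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """(n, 2) class probabilities, batch order preserved."""
        out = []
        for i in range(0, len(narrow), batch_size):
            logits = self.forward(narrow[i:i + batch_size], wide[i:i + batch_size])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0) if out else np.zeros((0, 2))

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "BifocalNet":
        path = Path(path)
        cfg_dict = json.loads(path.with_suffix(".json").read_text())
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        model = cls(BCNNConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def build_model(config: BCNNConfig | None = None) -> BifocalNet:
    """Construct a bifocal network with seed-deterministic initial weights."""
    return BifocalNet(config or BCNNConfig())


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def _standardize(img: np.ndarray) -> np.ndarray:
    """[0,1] HWC float image -> zero-centred HWC float32."""
    return (img.astype(np.float32) - 0.5) / 0.5


def pairs_to_arrays(pairs: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack BifocalPatchPair objects into (narrow, wide, labels) arrays."""
    narrow = np.stack([_standardize(p.narrow) for p in pairs])
    wide = np.stack([_standardize(p.wide) for p in pairs])
    labels = np.array([1 if p.label == "positive" else 0 for p in pairs])
    return narrow, wide, labels


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_order(labels: np.ndarray, rng: np.random.Generator,
                 balanced: bool) -> np.ndarray:
    """Index order for one epoch; class-balanced interleaving if requested."""
    if not balanced:
        return rng.permutation(len(labels))
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n = max(len(pos), len(neg))
    # oversample the minority class so each epoch sees both classes equally
    pos_idx = rng.permutation(np.resize(rng.permutation(pos), n))
    neg_idx = rng.permutation(np.resize(rng.permutation(neg), n))
    order = np.empty(2 * n, dtype=np.int64)
    order[0::2], order[1::2] = pos_idx, neg_idx
    return order


def train(model: BifocalNet, pairs: Sequence, config: BCNNConfig | None = None,
          validation: Sequence | None = None,
          epochs: int | None = None) -> dict:
    """Fit the bifocal net; returns a history dict of per-epoch stats.

    `pairs` may be a sequence of BifocalPatchPair or a pre-stacked
    (narrow, wide, labels) tuple. Raises on a single-class training set.
    """
    config = config or model.config
    if isinstance(pairs, tuple):
        narrow, wide, labels = pairs
    else:
        if len(pairs) == 0:
            raise ValueError("empty training set")
        narrow, wide, labels = pairs_to_arrays(pairs)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; need both")

    n_epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed + 1)
    n_per_epoch = 2 * max((labels == 1).sum(), (labels == 0).sum()) \
        if config.balanced_sampling else len(labels)
    steps_per_epoch = int(np.ceil(n_per_epoch / config.batch_size))
    opt = SGD(model.params(), lr=config.learning_rate, momentum=config.momentum,
              weight_decay=config.weight_decay, lr_min=config.lr_min,
              total_steps=steps_per_epoch * n_epochs)

    val_arrays = None
    if validation is not None:
        val_arrays = validation if isinstance(validation, tuple) \
            else pairs_to_arrays(validation)

    history: dict = {"loss": [], "lr": [], "val_accuracy": [], "val_auc": []}
    for _ in range(n_epochs):
        order = _epoch_order(labels, rng, config.balanced_sampling)
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(narrow[idx], wide[idx])
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(float(opt.lr))
        if val_arrays is not None:
            vn, vw, vl = val_arrays
            scores = model.predict_proba(vn, vw)[:, 1]
            history["val_accuracy"].append(float(((scores >= 0.5) == vl).mean()))
            if len(np.unique(vl)) == 2:
                fpr, tpr, _ = roc_curve(vl, scores)
                history["val_auc"].append(float(_auc(fpr, tpr)))
    return history


def predict_pairs(model: BifocalNet, pairs: Sequence,
                  batch_size: int = 256) -> np.ndarray:
    """Positive-class score in [0,1] per pair, in input order."""
    if isinstance(pairs, tuple):
        narrow, wide = pairs[0], pairs[1]
    else:
        if len(pairs) == 0:
            return np.zeros(0)
        narrow, wide, _ = pairs_to_arrays(pairs)
    return model.predict_proba(narrow, wide, batch_size=batch_size)[:, 1]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Binary-classification report: confusion matrix and ranking metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    roc_fpr: list[float] = field(repr=False, default_factory=list)
    roc_tpr: list[float] = field(repr=False, default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def confusion_matrix(self) -> np.ndarray:
        """Rows = true class (neg, pos); columns = predicted (neg, pos)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Confusion matrix at `threshold` plus threshold-free ROC/AUC.

    Raises if only one class is present (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: evaluation set contains one class only")

    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    fpr, tpr, _ = roc_curve(labels, scores)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / len(labels),
        precision=precision, recall=recall, specificity=specificity, f1=f1,
        auc=float(_auc(fpr, tpr)),
        roc_fpr=[float(v) for v in fpr], roc_tpr=[float(v) for v in tpr],
    )
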