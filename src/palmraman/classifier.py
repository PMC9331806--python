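"""Ripeness classification with a small multilayer perceptron.

The network mirrors the study setup: 7 selected spectral features in, one
hidden layer of 20 logistic-sigmoid units, 3 softmax outputs for under-ripe /
ripe / over-ripe, trained by full-batch gradient descent on mean cross-entropy
with an adaptive step and early stopping on a held-out validation set
(best-validation weights are restored).  Data are split 60/10/30 into
train/validation/test with largest-remainder rounding — 47 samples give
28/5/14, i.e. 33 fruits for training+validation and 14 for testing — and
features are standardized with statistics computed on the training partition
only.  The implementation is plain numpy so the loss, gradients and per-epoch
curves are fully inspectable (the analytic gradient is verified against
finite differences in the test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("palmraman")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions with largest-remainder rounding."""

    fractions: Tuple[float, float, float] = (0.60, 0.10, 0.30)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")


def _largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    """Apportion ``n`` items by the largest-remainder rule (ties to earlier parts)."""
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(labels: Sequence[str], spec: SplitSpec = SplitSpec()
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index partition into (train, validation, test).

    Global partition sizes follow the largest-remainder rule on the requested
    fractions (47 samples at 60/10/30 gives 28/5/14).  With ``stratified``
    each class is apportioned the same way and per-class allocations are then
    reconciled so the global sizes hold exactly — with only 47 fruits in three
    classes an unstratified draw can easily leave a class out of the
    5-sample validation set.  Deterministic under ``spec.seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 3:
        raise ValueError("cannot split fewer than 3 samples three ways")
    if n < 10:
        logger.warning("splitting only %d samples; partitions will be degenerate", n)
    target = _largest_remainder(n, spec.fractions)
    # guarantee non-empty partitions on tiny datasets by borrowing from the largest
    while min(target) == 0:
        target[int(np.argmax(target))] -= 1
        target[int(np.argmin(target))] += 1
        logger.warning("partition sizes adjusted to %s to avoid an empty split", target)
    rng = np.random.default_rng(spec.seed)
    parts: List[List[int]] = [[], [], []]
    if not spec.stratified:
        perm = rng.permutation(n)
        edges = np.cumsum(target)
        parts = [list(perm[:edges[0]]), list(perm[edges[0]:edges[1]]),
                 list(perm[edges[1]:])]
    else:
        classes = list(dict.fromkeys(labels))
        alloc: Dict[str, List[int]] = {}
        for c in classes:
            alloc[c] = _largest_remainder(int(np.sum(labels == c)), spec.fractions)
        # reconcile per-class allocations with the global targets by moving
        # single samples between partitions, preferring the largest class
        for p in range(3):
            while sum(a[p] for a in alloc.values()) > target[p]:
                # move one from partition p to the most under-filled partition q
                deficits = [target[q] - sum(a[q] for a in alloc.values()) for q in range(3)]
                q = int(np.argmax(deficits))
                donor = max((c for c in classes if alloc[c][p] > 0),
                            key=lambda c: alloc[c][p])
                alloc[donor][p] -= 1
                alloc[donor][q] += 1
        for c in classes:
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            a, b = alloc[c][0], alloc[c][0] + alloc[c][1]
            parts[0] += list(idx[:a])
            parts[1] += list(idx[a:b])
            parts[2] += list(idx[b:])
    out = tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)
    assert [len(p) for p in out] == target
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaler:
    """Per-feature zero-mean/unit-variance transform fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # flags for zero-variance features (scale forced to 1)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale


def impute_column_mean(X: np.ndarray) -> np.ndarray:
    """Replace missing entries by their column mean (undefined features of
    samples whose band component was pruned); all-missing columns become 0."""
    X = np.array(X, dtype=float)
    if np.any(np.isnan(X)):
        means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        idx = np.argwhere(np.isnan(X))
        logger.warning("imputed %d missing feature value(s) with column means",
                       idx.shape[0])
        X[np.isnan(X)] = means[idx[:, 1]]
    return X


def standardize(train: np.ndarray, *others: np.ndarray
                ) -> Tuple[List[np.ndarray], Scaler]:
    """Fit a scaler on ``train`` only and apply it to every partition."""
    train = np.asarray(train, float)
    if train.size == 0:
        raise ValueError("training partition is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    constant = sd == 0.0
    if np.any(constant):
        logger.warning("constant feature column(s) %s left unscaled",
                       np.flatnonzero(constant).tolist())
    scale = np.where(constant, 1.0, sd)
    scaler = Scaler(mean, scale, constant)
    return [scaler.transform(a) for a in (train, *others)], scaler


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training hyperparameters of the 7-20-3 network."""

    n_inputs: int = 7
    n_hidden: int = 20
    n_outputs: int = 3
    max_epochs: int = 200
    #: epochs without a new best validation loss before training stops; the
    #: default equals max_epochs because a 5-sample validation set gives a CE
    #: estimate far too noisy to gate training on — best-validation weights
    #: are restored either way, which is what protects against overfitting
    patience: int = 200
    learning_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_inputs, self.n_hidden, self.n_outputs) <= 0:
            raise ValueError("layer sizes must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingReport:
    """Per-epoch cross-entropy curves and the early-stopping outcome."""

    train_curve: List[float] = field(default_factory=list)
    val_curve: List[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_ce: float = float("inf")
    epochs_run: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax (stable); rows are non-negative and sum to one."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPModel:
    """7-20-3 perceptron: logistic hidden layer, softmax output."""

    def __init__(self, config: MLPConfig, classes: Sequence[str]):
        if len(classes) != config.n_outputs:
            raise ValueError("one output unit per class required")
        self.config = config
        self.classes = tuple(classes)
        rng = np.random.default_rng(config.seed)
        s1 = 1.0 / np.sqrt(config.n_inputs)
        s2 = 1.0 / np.sqrt(config.n_hidden)
        self.params = {
            "W1": rng.normal(0, s1, (config.n_inputs, config.n_hidden)),
            "b1": np.zeros(config.n_hidden),
            "W2": rng.normal(0, s2, (config.n_hidden, config.n_outputs)),
            "b2": np.zeros(config.n_outputs),
        }

    # forward ---------------------------------------------------------------
    def forward(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, float)
        H = _sigmoid(X @ self.params["W1"] + self.params["b1"])
        P = softmax(H @ self.params["W2"] + self.params["b2"])
        return P, H

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class indices; ties resolve to the lower class index."""
        return np.argmax(self.predict_proba(X), axis=1)

    # loss / gradient -------------------------------------------------------
    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Mean cross-entropy per sample against one-hot targets ``Y``."""
        P, _ = self.forward(X)
        eps = 1e-300
        return float(-np.mean(np.sum(Y * np.log(P + eps), axis=1)))

    def loss_and_grad(self, X: np.ndarray, Y: np.ndarray
                      ) -> Tuple[float, Dict[str, np.ndarray]]:
        """Analytic backpropagation gradient of the mean cross-entropy."""
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        n = X.shape[0]
        P, H = self.forward(X)
        loss = float(-np.mean(np.sum(Y * np.log(P + 1e-300), axis=1)))
        dZ2 = (P - Y) / n                      # softmax + CE shortcut
        dW2 = H.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dH = dZ2 @ self.params["W2"].T
        dZ1 = dH * H * (1.0 - H)               # logistic derivative
        dW1 = X.T @ dZ1
        db1 = dZ1.sum(axis=0)
        return loss, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    # persistence -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": vars(self.config) | {},
            "classes": list(self.classes),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        config = MLPConfig(**d["config"])
        model = cls(config, d["classes"])
        model.params = {k: np.asarray(v, float) for k, v in d["params"].items()}
        return model


def one_hot(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    classes = list(classes)
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y


def train_mlp(X_train: np.ndarray, y_train: Sequence[str],
              X_val: np.ndarray, y_val: Sequence[str],
              config: MLPConfig = MLPConfig(),
              classes: Optional[Sequence[str]] = None
              ) -> Tuple[MLPModel, TrainingReport]:
    """Full-batch adaptive gradient descent with validation early stopping.

    Each epoch takes one gradient step; if the step would increase the
    training loss it is halved (backtracking) until it decreases, so the
    training curve is non-increasing by construction.  Training stops when the
    validation cross-entropy has not improved for ``patience`` epochs or at
    ``max_epochs``; the best-validation weights are restored.
    """
    if classes is None:
        classes = list(dict.fromkeys(list(y_train) + list(y_val)))
    model = MLPModel(config, classes)
    Y_train = one_hot(y_train, classes)
    Y_val = one_hot(y_val, classes)
    report = TrainingReport()
    lr = config.learning_rate
    best_params = {k: v.copy() for k, v in model.params.items()}
    loss, grad = model.loss_and_grad(X_train, Y_train)
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        stepped = False
        for _ in range(40):
            trial = {k: model.params[k] - lr * grad[k] for k in model.params}
            saved = model.params
            model.params = trial
            new_loss = model.loss(X_train, Y_train)
            if np.isfinite(new_loss) and new_loss <= loss:
                stepped = True
                lr *= 1.1
                break
            model.params = saved
            lr *= 0.5
        if not np.isfinite(new_loss):
            raise FloatingPointError("non-finite training loss; aborting")
        if not stepped:
            logger.debug("epoch %d: step rejected at minimal rate; stopping", epoch)
            report.epochs_run = epoch
            break
        loss, grad = model.loss_and_grad(X_train, Y_train)
        val_ce = model.loss(X_val, Y_val)
        report.train_curve.append(loss)
        report.val_curve.append(val_ce)
        report.epochs_run = epoch
        if val_ce < report.best_val_ce - 1e-12:
            report.best_val_ce = val_ce
            report.best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.params = best_params
    logger.info("training stopped at epoch %d (best epoch %d, val CE %.6f)",
                report.epochs_run, report.best_epoch, report.best_val_ce)
    return model, report


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """3-class counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: Tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.classes),) * 2:
            raise ValueError("counts must be square in the number of classes")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Fraction correct: trace over total."""
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def accuracy_percent(self) -> float:
        """Accuracy in percent, rounded to one decimal (reporting convention)."""
        return round(100.0 * self.accuracy, 1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion_matrix(y_true: Sequence[str], y_pred_idx: np.ndarray,
                     classes: Sequence[str]) -> ConfusionMatrix:
    classes = tuple(classes)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for lab, pred in zip(y_true, y_pred_idx):
        counts[classes.index(lab), int(pred)] += 1
    return ConfusionMatrix(counts, classes)


def evaluate(model: MLPModel, partitions: Dict[str, Tuple[np.ndarray, Sequence[str]]]
             ) -> Dict[str, ConfusionMatrix]:
    """Confusion matrix per partition plus their elementwise-sum ``combined``."""
    out: Dict[str, ConfusionMatrix] = {}
    combined = None
    for name, (X, y) in partitions.items():
        if len(y) == 0:
            raise ValueError(f"partition {name!r} is empty")
        cm = confusion_matrix(y, model.predict(X), model.classes)
        out[name] = cm
        combined = cm if combined is None else combined + cm
    out["combined"] = combined
    return out


def save_model(model: MLPModel, scaler: Scaler, path,
               selected_features: Sequence[str] = ()) -> None:
    """Persist weights, scaler and configuration as plain JSON."""
    payload = model.to_dict()
    payload["scaler"] = {"mean": scaler.mean.tolist(), "scale": scaler.scale.tolist(),
                         "constant": scaler.constant.tolist()}
    payload["selected_features"] = list(selected_features)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> Tuple[MLPModel, Scaler, List[str]]:
    d = json.loads(Path(path).read_text())
    model = MLPModel.from_dict(d)
    s = d["scaler"]
    scaler = Scaler(np.asarray(s["mean"]), np.asarray(s["scale"]),
                    np.asarray(s["constant"], dtype=bool))
    return model, scaler, d.get("selected_features", [])
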