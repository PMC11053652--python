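"""The RF-1D-CNN classifier and the SVM/RF/KNN comparison baselines.

The 1-D CNN consumes the channels retained by the random-forest ranking, in
spectral order, as a one-dimensional tensor.  Architecture: four convolution
layers (32/64/128/64 filters), two max-pooling layers (after conv-2 and
conv-4), three fully connected layers; batch normalization after each
convolution, each pooling stage and the first two dense layers; dropout
(p = 0.5) after the second dense layer; softmax output over two classes.
Optimization is SGD with momentum and L2 weight decay on the cross-entropy
loss; hyperparameters can be chosen by random search scored on validation
cross-entropy (optionally averaged over k folds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import nn
from .features import FeatureMask

__all__ = [
    "CNNConfig",
    "Hyperparams",
    "TrainedModel",
    "BaselineModel",
    "build_cnn",
    "train",
    "random_search",
    "train_baseline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNNConfig:
    conv_filters: tuple[int, int, int, int] = (32, 64, 128, 64)
    kernel_width: int = 5  # channels
    pool_after: tuple[int, int] = (2, 4)  # pooling follows these conv blocks
    fc_widths: tuple[int, int] = (256, 64)
    dropout: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("the architecture has exactly four convolution layers")
        if len(self.pool_after) != 2:
            raise ValueError("the architecture has exactly two pooling layers")
        if len(self.fc_widths) != 2:
            raise ValueError("the architecture has exactly three dense layers (two hidden)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class Hyperparams:
    batch_size: int = 64
    lr: float = 0.01
    dropout: float = 0.5
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 50
    patience: int | None = 10  # early stopping on validation loss; None disables

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class CNN:
    """The network plus its structural bookkeeping."""

    def __init__(self, cfg: CNNConfig, input_len: int, seed: int = 0):
        if input_len < 16:
            raise ValueError(f"input length {input_len} too short for two pooling stages")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_len = input_len
        k = cfg.kernel_width
        layers: list[nn.Layer] = []
        c_in, length = 1, input_len
        for i, c_out in enumerate(cfg.conv_filters, start=1):
            layers += [nn.Conv1d(c_in, c_out, k, rng), nn.BatchNorm(c_out), nn.ReLU()]
            c_in = c_out
            if i in cfg.pool_after:
                layers += [nn.MaxPool1d(), nn.BatchNorm(c_out)]
                length //= 2
        layers.append(nn.Flatten())
        width = c_in * length
        self._dropout_rng = np.random.default_rng(seed + 1)
        for w in cfg.fc_widths:
            layers += [nn.Dense(width, w, rng), nn.BatchNorm(w), nn.ReLU()]
            width = w
        # dropout after the second dense block, then the output layer
        layers.insert(len(layers), nn.Dropout(cfg.dropout, self._dropout_rng))
        layers.append(nn.Dense(width, cfg.n_classes, rng))
        self.net = nn.Network(layers)

    def audit(self) -> dict[str, int]:
        """Count layers by kind — the structural contract of the architecture."""
        counts = {"conv": 0, "pool": 0, "fc": 0, "batchnorm": 0, "dropout": 0}
        for layer in self.net.layers:
            if isinstance(layer, nn.Conv1d):
                counts["conv"] += 1
            elif isinstance(layer, nn.MaxPool1d):
                counts["pool"] += 1
            elif isinstance(layer, nn.Dense):
                counts["fc"] += 1
            elif isinstance(layer, nn.BatchNorm):
                counts["batchnorm"] += 1
            elif isinstance(layer, nn.Dropout):
                counts["dropout"] += 1
        return counts

    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(X, dtype=nn.F32)[:, :, None]
        return self.net.forward(x, train=train)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(X, train=False).astype(float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def build_cnn(cfg: CNNConfig, input_len: int, seed: int = 0) -> CNN:
    """Construct an untrained network for the given input length."""
    return CNN(cfg, input_len, seed=seed)


@dataclass
class TrainedModel:
    """A trained classifier plus everything inference needs to be self-describing."""

    kind: str
    model: object  # CNN or fitted sklearn estimator
    mask: FeatureMask | None = None
    normalization: str = "none"
    seed: int | None = None
    history: dict = field(default_factory=dict)
    hyperparams: Hyperparams | None = None

    def _inputs(self, X: np.ndarray) -> np.ndarray:
        from .preprocess import normalize_matrix

        X = np.asarray(X, dtype=float)
        if self.normalization != "none":
            X = normalize_matrix(X, self.normalization)
        if self.mask is not None:
            X = self.mask.apply(X)
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self._inputs(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def _epoch(cnn: CNN, X, y, opt: nn.SGD, rng: np.random.Generator, batch_size: int) -> float:
    idx = rng.permutation(X.shape[0])
    total = 0.0
    for start in range(0, idx.size, batch_size):
        b = idx[start : start + batch_size]
        logits = cnn.logits(X[b], train=True)
        loss, grad = nn.cross_entropy_grad(logits, y[b])
        cnn.net.backward(grad)
        opt.step()
        total += loss * b.size
    return total / idx.size


def _eval_loss(cnn: CNN, X, y, batch_size: int = 256) -> tuple[float, float]:
    losses, correct = 0.0, 0
    for start in range(0, X.shape[0], batch_size):
        logits = cnn.logits(X[start : start + batch_size], train=False)
        loss, _ = nn.cross_entropy_grad(logits, y[start : start + batch_size])
        losses += loss * logits.shape[0]
        correct += int((logits.argmax(axis=1) == y[start : start + batch_size]).sum())
    return losses / X.shape[0], correct / X.shape[0]


def train(model: CNN | None, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray], hp: Hyperparams, seed: int = 0,
          cfg: CNNConfig | None = None, mask: FeatureMask | None = None) -> TrainedModel:
    """Train the CNN with SGD(momentum, weight decay) on cross-entropy.

    Records per-epoch training and validation losses; with ``hp.patience`` set,
    stops when the validation loss has not improved for that many epochs and
    restores the best-validation-loss weights.  Deterministic given ``seed``.
    """
    Xtr, ytr = np.asarray(train_set[0], float), np.asarray(train_set[1], int)
    Xva, yva = np.asarray(val_set[0], float), np.asarray(val_set[1], int)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if np.unique(ytr).size < 2:
        raise ValueError("training set must contain both classes")
    if model is None:
        cfg = replace(cfg or CNNConfig(), dropout=hp.dropout)
        model = build_cnn(cfg, Xtr.shape[1], seed=seed)
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.net.params, lr=hp.lr, momentum=hp.momentum, weight_decay=hp.weight_decay)
    Xtr32 = Xtr.astype(nn.F32)
    Xva32 = Xva.astype(nn.F32)
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss, best_weights, since_best = np.inf, None, 0
    for epoch in range(hp.epochs):
        tr_loss = _epoch(model, Xtr32, ytr, opt, rng, hp.batch_size)
        va_loss, va_acc = _eval_loss(model, Xva32, yva)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_loss < best_loss - 1e-12:
            best_loss, best_weights, since_best = va_loss, model.net.get_weights(), 0
        else:
            since_best += 1
        if hp.patience is not None and since_best > hp.patience:
            log.info("early stop at epoch %d (best val loss %.4g)", epoch + 1, best_loss)
            break
    if hp.patience is not None and best_weights is not None:
        model.net.set_weights(best_weights)
    return TrainedModel(kind="rf-1d-cnn", model=model, mask=mask, normalization="none",
                        seed=seed, history=history, hyperparams=hp)


def random_search(space: dict[str, Sequence | tuple[float, float]],
                  X: np.ndarray, y: np.ndarray, budget: int = 30, folds: int = 5,
                  seed: int = 0, cfg: CNNConfig | None = None,
                  base: Hyperparams | None = None) -> tuple[Hyperparams, list[dict]]:
    """Random hyperparameter search scored by mean validation cross-entropy.

    ``space`` maps Hyperparams field names to either an explicit list of
    candidate values or a (lo, hi) range sampled uniformly (log-uniformly when
    both endpoints are positive and more than two decades apart).  With
    ``folds`` > 1 each configuration is scored by k-fold cross-validation on
    (X, y); with ``folds`` == 1 a single 80/20 split is used.  Returns the
    minimizer and the full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    base = base or Hyperparams()
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n = X.shape[0]

    def sample() -> Hyperparams:
        kw = {}
        for key, spec in space.items():
            if isinstance(spec, tuple) and len(spec) == 2 and all(
                isinstance(v, (int, float)) for v in spec
            ):
                lo, hi = spec
                if lo > 0 and hi / lo > 100:
                    val = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
                else:
                    val = rng.uniform(lo, hi)
            else:
                val = spec[rng.integers(len(spec))]
            if key == "batch_size":
                val = int(val)
            kw[key] = val
        return replace(base, **kw)

    perm = rng.permutation(n)
    fold_idx = np.array_split(perm, max(folds, 2)) if folds > 1 else None
    log_rows: list[dict] = []
    best_hp, best_score = None, np.inf
    for trial in range(budget):
        hp = sample()
        scores = []
        if folds > 1:
            for i in range(folds):
                va = fold_idx[i]
                tr = np.concatenate([fold_idx[j] for j in range(folds) if j != i])
                tm = train(None, (X[tr], y[tr]), (X[va], y[va]), hp,
                           seed=seed + trial, cfg=cfg)
                scores.append(min(tm.history["val_loss"]))
        else:
            cut = int(round(0.8 * n))
            tr, va = perm[:cut], perm[cut:]
            tm = train(None, (X[tr], y[tr]), (X[va], y[va]), hp,
                       seed=seed + trial, cfg=cfg)
            scores.append(min(tm.history["val_loss"]))
        score = float(np.mean(scores))
        if not np.isfinite(score):  # diverged configuration
            score = float("inf")
        log_rows.append({"trial": trial, "score": score, **{k: getattr(hp, k) for k in space}})
        if score < best_score:
            best_score, best_hp = score, hp
    return best_hp, log_rows


_BASELINES = ("svm", "rf", "knn")


def train_baseline(kind: str, X: np.ndarray, y: np.ndarray,
                   params: dict | None = None, seed: int = 0,
                   normalization: str = "none",
                   mask: FeatureMask | None = None) -> TrainedModel:
    """Fit one of the comparison classifiers behind the shared predict interface.

    ``X`` must already be preprocessed as the caller intends (the fitted model
    records ``normalization``/``mask`` so inference re-applies them to raw
    corrected spectra).
    """
    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {_BASELINES}")
    params = dict(params or {})
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if kind == "svm":
        clf = SVC(probability=True, random_state=seed, **params)
    elif kind == "rf":
        params.setdefault("n_estimators", 50)
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        params.setdefault("n_neighbors", 5)
        clf = KNeighborsClassifier(**params)
    clf.fit(X, y)
    return TrainedModel(kind=kind, model=clf, mask=mask, normalization=normalization, seed=seed)
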