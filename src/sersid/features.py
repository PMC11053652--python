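"""Random-forest importance ranking of spectral channels and top-K selection.

A classification forest (Gini impurity, bootstrap) is fit on the training set
only; mean impurity decrease per channel gives the ranking and the K most
important channels are retained *in ascending spectral order*, so the reduced
vector is still a meaningful 1-D sequence for convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["ForestConfig", "FeatureRanking", "FeatureMask", "rank_importance", "select_top"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 50
    max_features: int = 100  # candidate features per split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass(frozen=True)
class FeatureRanking:
    """Normalized importance per channel plus the descending-importance order."""

    scores: np.ndarray  # sums to 1
    order: np.ndarray  # permutation of channel indices, best first

    def __post_init__(self) -> None:
        if sorted(self.order.tolist()) != list(range(self.scores.size)):
            raise ValueError("order must be a permutation of channel indices")


@dataclass(frozen=True)
class FeatureMask:
    """Sorted retained channel indices."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.indices.size != self.k:
            raise ValueError("mask size must equal K")
        if self.indices.size != np.unique(self.indices).size:
            raise ValueError("mask indices must be unique")

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.indices]

    def save(self, path: str | Path, grid=None) -> None:
        payload = {"k": int(self.k), "indices": self.indices.tolist()}
        if grid is not None:
            payload["grid"] = {"lo": grid.lo, "hi": grid.hi, "n": grid.n}
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "FeatureMask":
        payload = json.loads(Path(path).read_text())
        return FeatureMask(np.array(payload["indices"], dtype=int), payload["k"])


def rank_importance(X: np.ndarray, y: np.ndarray, cfg: ForestConfig = ForestConfig()) -> FeatureRanking:
    """Fit the ranking forest on training data and return per-channel importance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("importance ranking needs at least two classes")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_features=min(cfg.max_features, X.shape[1]),
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    scores = clf.feature_importances_.astype(float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    else:
        scores = np.full(X.shape[1], 1.0 / X.shape[1])
    order = np.argsort(-scores, kind="stable")  # ties broken by channel index
    return FeatureRanking(scores=scores, order=order)


def select_top(X: np.ndarray, ranking: FeatureRanking, k: int) -> tuple[np.ndarray, FeatureMask]:
    """Retain the k highest-importance channels, columns in ascending spectral order."""
    X = np.asarray(X)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"K must be in [1, {X.shape[1]}], got {k}")
    idx = np.sort(ranking.order[:k])
    mask = FeatureMask(indices=idx, k=k)
    return mask.apply(X), mask
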