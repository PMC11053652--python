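"""Spectral data augmentation and dataset division.

Three augmentation moves expand a small measured set while preserving class
identity: (a) small random translation along the shift axis, (b) additive
Gaussian noise, and (c) convex combinations of spectra of the same analyte at
the same concentration (coefficients summing to 1).  Combinations never cross
(analyte, concentration) strata — mixing across strata would fabricate
chemistry the labels do not describe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Spectrum, SpectrumSet

__all__ = [
    "AugmentConfig",
    "SplitConfig",
    "shift_spectrum",
    "add_noise",
    "convex_combine",
    "expand_dataset",
    "split_dataset",
    "kfold",
    "assemble_binary",
]

log = logging.getLogger(__name__)

_METHODS = ("shift", "noise", "combine")


@dataclass(frozen=True)
class AugmentConfig:
    factor: int = 6
    max_shift: int = 5  # channels (≈ ±8 cm⁻¹ on the default grid)
    sigma_aug: float = 0.02  # fraction of each spectrum's maximum
    probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # P(shift), P(noise), P(combine)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.sigma_aug < 0:
            raise ValueError("sigma_aug must be >= 0")
        if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
            raise ValueError("method probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    stratified: bool = True
    k: int = 5
    seed: int = 0
    #: Keep augmented siblings (spectra sharing a raw parent) on one side of the
    #: split.  The reference protocol splits after augmentation, so siblings may
    #: straddle the boundary; this flag enables the leakage-safe alternative.
    group_by_parent: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def shift_spectrum(y: np.ndarray, k: int, max_shift: int) -> np.ndarray:
    """Translate by k channels (positive = toward higher shifts), edge-filled."""
    y = np.asarray(y, dtype=float)
    if abs(k) > max_shift:
        raise ValueError(f"|k|={abs(k)} exceeds max shift {max_shift}")
    if max_shift >= y.size:
        raise ValueError("max shift must be smaller than the spectrum length")
    out = np.empty_like(y)
    if k == 0:
        out[:] = y
    elif k > 0:
        out[k:] = y[:-k]
        out[:k] = y[0]
    else:
        out[:k] = y[-k:]
        out[k:] = y[-1]
    return out


def add_noise(y: np.ndarray, sigma_aug: float, seed: int) -> np.ndarray:
    """Add Gaussian noise with s.d. sigma_aug × max(y); deterministic given seed."""
    y = np.asarray(y, dtype=float)
    if sigma_aug < 0:
        raise ValueError("sigma_aug must be >= 0")
    if sigma_aug == 0:
        return y.copy()
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, sigma_aug * float(y.max()), y.size)


def convex_combine(spectra: list[Spectrum], weights) -> Spectrum:
    """Channel-wise convex combination of same-analyte, same-concentration spectra."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to combine")
    w = np.asarray(weights, dtype=float)
    if w.size != len(spectra) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1 (one per spectrum)")
    keys = {(s.meta.get("analyte"), s.meta.get("concentration_M")) for s in spectra}
    if len(keys) != 1:
        raise ValueError("convex combination requires matching analyte and concentration labels")
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.shifts, ref.shifts):
            raise ValueError("grids differ between spectra")
    y = sum(wi * s.intensities for wi, s in zip(w, spectra))
    meta = dict(ref.meta)
    meta["provenance"] = "augmented"
    return Spectrum(ref.shifts.copy(), y, meta)


def expand_dataset(raw: SpectrumSet, cfg: AugmentConfig) -> SpectrumSet:
    """Expand a raw set by cfg.factor (originals included in the output).

    Each original receives factor−1 augmented children; the move for each child
    is drawn from cfg.probs.  Children record their method and parent row
    indices.  A stratum with a single spectrum cannot support combination and
    falls back to shift/noise (logged).
    """
    if len(raw) == 0:
        raise ValueError("raw dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    key = list(zip(raw.meta["analyte"], raw.meta["concentration_M"]))
    strata: dict = {}
    for i, k in enumerate(key):
        strata.setdefault(k, []).append(i)

    rows_X = [raw.X]
    rows_meta = [raw.meta.assign(method="original", parents=[str(i) for i in range(len(raw))])]
    new_X, new_meta = [], []
    for i in range(len(raw)):
        sib = strata[key[i]]
        for _ in range(cfg.factor - 1):
            method = _METHODS[rng.choice(3, p=cfg.probs)]
            if method == "combine" and len(sib) < 2:
                method = _METHODS[rng.choice(2)]
                log.warning("stratum %s has a single spectrum; combine fell back to %s",
                            key[i], method)
            if method == "shift":
                k = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
                y = shift_spectrum(raw.X[i], k, cfg.max_shift)
                parents = str(i)
            elif method == "noise":
                y = raw.X[i] + rng.normal(0.0, cfg.sigma_aug * float(raw.X[i].max()), raw.X.shape[1])
                parents = str(i)
            else:
                j = int(rng.choice([s for s in sib if s != i]))
                w = float(rng.uniform(0.0, 1.0))
                y = w * raw.X[i] + (1.0 - w) * raw.X[j]
                parents = f"{i},{j}"
            new_X.append(y)
            m = raw.meta.iloc[i].to_dict()
            m["provenance"] = "augmented"
            m["method"] = method
            m["parents"] = parents
            new_meta.append(m)
    if new_X:
        rows_X.append(np.vstack(new_X))
        rows_meta.append(pd.DataFrame(new_meta))
    out = SpectrumSet(raw.shifts, np.vstack(rows_X), pd.concat(rows_meta, ignore_index=True))
    assert len(out) == len(raw) * cfg.factor
    return out


def _stratified_counts(n_per_class: dict, n_train: int) -> dict:
    """Per-class training counts: proportional allocation, largest-remainder rounding."""
    total = sum(n_per_class.values())
    quotas = {c: n_train * n / total for c, n in n_per_class.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n_train - sum(counts.values())
    order = sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def split_dataset(ds: SpectrumSet, cfg: SplitConfig) -> tuple[SpectrumSet, SpectrumSet]:
    """Disjoint, exhaustive train/validation partition, optionally class-stratified."""
    n = len(ds)
    if n < 2:
        raise ValueError("dataset too small to split")
    n_train = int(round(cfg.train_fraction * n))
    rng = np.random.default_rng(cfg.seed)
    if cfg.group_by_parent and "parents" in ds.meta.columns:
        comp = _parent_components(ds.meta["parents"])
        groups = sorted(set(comp))
        order = rng.permutation(len(groups))
        mask = np.zeros(n, dtype=bool)
        taken = 0
        for gi in order:
            idx = [i for i, c in enumerate(comp) if c == groups[gi]]
            if taken >= n_train:
                break
            mask[idx] = True
            taken += len(idx)
        return ds.subset(mask), ds.subset(~mask)
    if cfg.stratified:
        labels = ds.labels
        classes, _ = np.unique(labels, return_counts=True)
        per_class = {c: int((labels == c).sum()) for c in classes}
        counts = _stratified_counts(per_class, n_train)
        train_idx = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            train_idx.append(idx[: counts[c]])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        idx = rng.permutation(n)
        train_idx = np.sort(idx[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return ds.subset(mask), ds.subset(~mask)


def _parent_components(parents: pd.Series) -> list[int]:
    """Union-find over parent ids: convex combinations link two raw parents, so
    each row is assigned the connected component of its ancestry."""
    root: dict[int, int] = {}

    def find(a: int) -> int:
        while root.setdefault(a, a) != a:
            root[a] = root[root[a]]
            a = root[a]
        return a

    parsed = [tuple(int(p) for p in str(s).split(",")) for s in parents]
    for ids in parsed:
        for b in ids[1:]:
            root[find(ids[0])] = find(b)
    return [find(ids[0]) for ids in parsed]


def kfold(ds: SpectrumSet, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint index folds covering the dataset, sizes differing by at most 1."""
    n = len(ds)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]


def assemble_binary(positive: SpectrumSet, negatives: list[SpectrumSet],
                    n_pos: int, n_per_neg: int, seed: int) -> SpectrumSet:
    """Draw the binary-classification dataset: n_pos positives (label 1) plus
    n_per_neg spectra from each negative source (label 0), without replacement."""
    rng = np.random.default_rng(seed)
    if len(positive) < n_pos:
        raise ValueError(f"need {n_pos} positives, have {len(positive)}")
    parts = [positive.subset(rng.choice(len(positive), n_pos, replace=False))]
    parts[0].meta["label"] = 1
    for neg in negatives:
        if len(neg) < n_per_neg:
            raise ValueError(f"need {n_per_neg} negatives per source, have {len(neg)}")
        sub = neg.subset(rng.choice(len(neg), n_per_neg, replace=False))
        sub.meta["label"] = 0
        parts.append(sub)
    return SpectrumSet.concat(parts)
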