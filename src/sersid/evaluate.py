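"""Confusion counting, accuracy/sensitivity/specificity, and the
mixture-identification test-set protocol.

The positive class (label 1) is the target analyte (thiram); metrics follow
the standard binary definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Undefined denominators are surfaced as ``None`` with an explicit flag, never
silently reported as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectrumSet

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "build_test_set",
    "evaluate_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    undefined: tuple[str, ...] = ()
    model: str = ""
    condition: str = ""

    def as_row(self) -> dict:
        pct = lambda v: round(100.0 * v, 1) if v is not None else None
        return {
            "model": self.model,
            "condition": self.condition,
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "accuracy_pct": pct(self.accuracy),
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
        }


def confusion(predicted, true) -> ConfusionCounts:
    """Exact TP/TN/FP/FN counts for binary labels (positive class = 1)."""
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and true labels must be equal-length 1-D arrays")
    for arr, name in ((p, "predicted"), (t, "true")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def metrics(c: ConfusionCounts, model: str = "", condition: str = "") -> MetricsReport:
    """Accuracy, sensitivity, specificity from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined = []
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        sens, undefined = None, undefined + ["sensitivity"]
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        spec, undefined = None, undefined + ["specificity"]
    return MetricsReport(counts=c, accuracy=acc, sensitivity=sens, specificity=spec,
                         undefined=tuple(undefined), model=model, condition=condition)


def build_test_set(positives: SpectrumSet, negatives: list[SpectrumSet],
                   n_pos: int = 20, n_per_neg: int = 5, seed: int = 0) -> SpectrumSet:
    """Assemble the mixture-identification test set.

    ``n_pos`` mixture spectra (label 1) plus ``n_per_neg`` spectra from each
    negative source (label 0), shuffled deterministically.  With the default
    counts and four negative sources this is the 40-spectrum, 20-positive
    protocol; other source counts are allowed and logged.
    """
    rng = np.random.default_rng(seed)
    if len(positives) < n_pos:
        raise ValueError(f"need {n_pos} positive spectra, have {len(positives)}")
    parts = [positives.subset(rng.choice(len(positives), n_pos, replace=False))]
    parts[0].meta["label"] = 1
    for neg in negatives:
        if len(neg) < n_per_neg:
            raise ValueError(f"need {n_per_neg} spectra per negative source, have {len(neg)}")
        sub = neg.subset(rng.choice(len(neg), n_per_neg, replace=False))
        sub.meta["label"] = 0
        parts.append(sub)
    out = SpectrumSet.concat(parts)
    if len(negatives) != 4:
        log.warning("test set uses %d negative sources (protocol default is 4); size %d",
                    len(negatives), len(out))
    order = rng.permutation(len(out))
    return out.subset(order)


def evaluate_pipeline(model, test_set: SpectrumSet, model_name: str = "",
                      condition: str = "", n_channels: int | None = None) -> MetricsReport:
    """Apply a trained model's stored preprocessing/mask to a test set and score it.

    The spectra in ``test_set`` must already be baseline-corrected on the grid
    the model was trained on; the model's own normalization and feature mask
    are applied internally.  Read-only: no model state changes.
    """
    if n_channels is not None and test_set.X.shape[1] != n_channels:
        raise ValueError(
            f"grid mismatch: model expects {n_channels} channels, "
            f"test set has {test_set.X.shape[1]}"
        )
    pred = model.predict(test_set.X)
    c = confusion(pred, test_set.labels)
    return metrics(c, model=model_name or getattr(model, "kind", ""), condition=condition)


def report_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Stack per-(model, condition) reports into the tabular report layout."""
    return pd.DataFrame([r.as_row() for r in reports])
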