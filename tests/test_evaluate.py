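import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_labeled_set
from sersid.evaluate import (
    ConfusionCounts,
    build_test_set,
    confusion,
    evaluate_pipeline,
    metrics,
    report_table,
)


class TestConfusion:
    def test_all_correct(self):
        true = np.array([1] * 20 + [0] * 20)
        c = confusion(true, true)
        assert (c.tp, c.tn, c.fp, c.fn) == (20, 20, 0, 0)

    def test_always_positive_predictor(self):
        true = np.array([1, 0, 1, 0, 0])
        c = confusion(np.ones(5, dtype=int), true)
        assert c.fn == 0 and c.tn == 0
        assert c.tp == 2 and c.fp == 3

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        p, t = rng.integers(0, 2, 137), rng.integers(0, 2, 137)
        assert confusion(p, t).total == 137

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 1, 1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            confusion([0, 2], [0, 1])


class TestMetrics:
    def test_svm_ternary_five_percent_row(self):
        """Counts implied by the printed 70/100/40 row on a 20/20 test set."""
        r = metrics(ConfusionCounts(tp=20, fn=0, tn=8, fp=12))
        assert (r.accuracy, r.sensitivity, r.specificity) == (0.70, 1.00, 0.40)

    def test_perfect_row(self):
        r = metrics(ConfusionCounts(20, 20, 0, 0))
        assert (r.accuracy, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_undefined_sensitivity_flagged(self):
        r = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert r.sensitivity is None
        assert "sensitivity" in r.undefined
        assert r.accuracy == 0.5

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_matches_brute_force_recount(self):
        """Property: metrics agree with a per-spectrum recount on random predictions."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(2, 60))
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            c = confusion(pred, true)
            tp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 1)
            tn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 0)
            fp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 0)
            fn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 1)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            r = metrics(c)
            assert r.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert r.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert r.specificity == pytest.approx(tn / (tn + fp))

    @settings(derandomize=True, max_examples=200)
    @given(tp=st.integers(0, 100), tn=st.integers(0, 100),
           fp=st.integers(0, 100), fn=st.integers(0, 100))
    def test_metric_bounds_and_total(self, tp, tn, fp, fn):
        """Every defined metric lies in [0, 1] and the counts conserve n."""
        if tp + tn + fp + fn == 0:
            return
        c = ConfusionCounts(tp, tn, fp, fn)
        r = metrics(c)
        assert c.total == tp + tn + fp + fn
        for v in (r.accuracy, r.sensitivity, r.specificity):
            assert v is None or 0.0 <= v <= 1.0

    def test_accuracy_identity(self):
        """accuracy == (sens*P + spec*N)/(P+N) whenever both are defined."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 30, 4))
            r = metrics(ConfusionCounts(tp, tn, fp, fn))
            P, N = tp + fn, tn + fp
            assert r.accuracy == pytest.approx(
                (r.sensitivity * P + r.specificity * N) / (P + N))


class _ConstantModel:
    def __init__(self, value: int):
        self.value = value

    def predict(self, X):
        return np.full(X.shape[0], self.value, dtype=int)


class TestTestSet:
    def _sources(self, small_grid):
        pos = make_labeled_set(small_grid, 30, "thiram+TBZ+CBZ", 1e-5, 1, seed=0)
        negs = [make_labeled_set(small_grid, 10, name, 1e-5, 0, seed=i)
                for i, name in enumerate(("TBZ", "CBZ", "phosmet", "substrate"))]
        return pos, negs

    def test_default_composition_40_20(self, small_grid):
        pos, negs = self._sources(small_grid)
        ts = build_test_set(pos, negs, n_pos=20, n_per_neg=5, seed=1)
        assert len(ts) == 40
        assert int((ts.labels == 1).sum()) == 20

    def test_three_negative_sources_gives_35(self, small_grid):
        pos, negs = self._sources(small_grid)
        ts = build_test_set(pos, negs[:3], n_pos=20, n_per_neg=5, seed=1)
        assert len(ts) == 35

    def test_insufficient_sources_rejected(self, small_grid):
        pos, negs = self._sources(small_grid)
        with pytest.raises(ValueError, match="positive"):
            build_test_set(pos, negs, n_pos=50, n_per_neg=5, seed=0)

    def test_deterministic_shuffle(self, small_grid):
        pos, negs = self._sources(small_grid)
        a = build_test_set(pos, negs, seed=4)
        b = build_test_set(pos, negs, seed=4)
        assert np.array_equal(a.X, b.X)
        assert a.meta["label"].tolist() == b.meta["label"].tolist()


class TestEvaluatePipeline:
    def test_constant_negative_predictor(self, small_grid):
        pos = make_labeled_set(small_grid, 30, "mix", 1e-5, 1, seed=0)
        negs = [make_labeled_set(small_grid, 30, "TBZ", 1e-5, 0, seed=1)]
        ts = build_test_set(pos, negs, n_pos=20, n_per_neg=20, seed=0)
        r = evaluate_pipeline(_ConstantModel(0), ts)
        assert r.accuracy == 0.5
        assert r.sensitivity == 0.0
        assert r.specificity == 1.0

    def test_grid_mismatch_rejected(self, small_grid):
        pos = make_labeled_set(small_grid, 25, "mix", 1e-5, 1, seed=0)
        ts = build_test_set(pos, [], n_pos=20, n_per_neg=0, seed=0)
        with pytest.raises(ValueError, match="grid mismatch"):
            evaluate_pipeline(_ConstantModel(0), ts, n_channels=900)

    def test_report_row_bookkeeping(self, small_grid):
        pos = make_labeled_set(small_grid, 30, "mix", 1e-5, 1, seed=0)
        negs = [make_labeled_set(small_grid, 30, "TBZ", 1e-5, 0, seed=1)]
        ts = build_test_set(pos, negs, n_pos=20, n_per_neg=20, seed=0)
        reports = [
            evaluate_pipeline(_ConstantModel(v), ts, model_name=m, condition=c)
            for m, v in (("a", 0), ("b", 1))
            for c in ("x", "y", "z")
        ]
        table = report_table(reports)
        assert len(table) == 6
        assert set(table.columns) >= {"model", "condition", "TP", "TN", "FP", "FN",
                                      "accuracy_pct", "sensitivity_pct", "specificity_pct"}
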