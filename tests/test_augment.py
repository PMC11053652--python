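from collections import Counter

import numpy as np
import pytest

from conftest import make_labeled_set
from sersid.augment import (
    AugmentConfig,
    SplitConfig,
    add_noise,
    convex_combine,
    expand_dataset,
    kfold,
    shift_spectrum,
    split_dataset,
)
from sersid.io import Grid, Spectrum, SpectrumSet


@pytest.fixture(scope="module")
def raw240(small_grid):
    """40 spectra x 6 concentrations of one analyte (the per-analyte raw set)."""
    sets = [
        make_labeled_set(small_grid, 40, "thiram", c, 1, seed=i)
        for i, c in enumerate((1e-4, 5e-5, 1e-5, 5e-6, 1e-6, 5e-7))
    ]
    return SpectrumSet.concat(sets)


class TestShift:
    def test_zero_shift_identity(self):
        y = np.arange(10.0)
        assert np.array_equal(shift_spectrum(y, 0, 5), y)

    def test_spike_translates(self):
        y = np.zeros(200)
        y[100] = 7.0
        out = shift_spectrum(y, 5, 5)
        assert out[105] == 7.0 and out.sum() == 7.0

    def test_edge_fill(self):
        y = np.arange(10.0)
        out = shift_spectrum(y, 3, 5)
        assert np.array_equal(out[:3], [0.0, 0.0, 0.0])
        out = shift_spectrum(y, -3, 5)
        assert np.array_equal(out[-3:], [9.0, 9.0, 9.0])

    def test_beyond_max_shift_rejected(self):
        with pytest.raises(ValueError, match="max shift"):
            shift_spectrum(np.arange(10.0), 6, 5)


class TestAddNoise:
    def test_zero_sigma_identity(self):
        y = np.arange(100.0)
        assert np.array_equal(add_noise(y, 0.0, seed=1), y)

    def test_noise_moment(self):
        y = np.full(10_000, 50.0)
        out = add_noise(y, 0.03, seed=1)
        assert np.std(out - y) == pytest.approx(0.03 * 50.0, rel=0.05)

    def test_deterministic(self):
        y = np.arange(100.0)
        assert np.array_equal(add_noise(y, 0.1, seed=3), add_noise(y, 0.1, seed=3))


class TestConvexCombine:
    def _pair(self):
        shifts = np.arange(10.0)
        meta = {"analyte": "thiram", "concentration_M": "1e-05"}
        return (Spectrum(shifts, np.ones(10), dict(meta)),
                Spectrum(shifts, np.full(10, 3.0), dict(meta)))

    def test_degenerate_weight_returns_first(self):
        a, b = self._pair()
        out = convex_combine([a, b], [1.0, 0.0])
        assert np.array_equal(out.intensities, a.intensities)

    def test_identical_inputs_fixed_point(self):
        a, _ = self._pair()
        out = convex_combine([a, a.copy()], [0.4, 0.6])
        assert np.allclose(out.intensities, a.intensities)

    def test_weights_must_sum_to_one(self):
        a, b = self._pair()
        with pytest.raises(ValueError, match="sum to 1"):
            convex_combine([a, b], [0.3, 0.8])

    def test_mismatched_labels_rejected(self):
        a, b = self._pair()
        b.meta["analyte"] = "TBZ"
        with pytest.raises(ValueError, match="matching analyte"):
            convex_combine([a, b], [0.5, 0.5])


class TestExpand:
    def test_240_to_1440(self, raw240):
        out = expand_dataset(raw240, AugmentConfig(factor=6, seed=0))
        assert len(out) == 1440

    def test_factor_one_is_identity(self, raw240):
        out = expand_dataset(raw240, AugmentConfig(factor=1, seed=0))
        assert np.array_equal(out.X, raw240.X)

    def test_label_multiset_conserved(self, small_grid):
        pos = make_labeled_set(small_grid, 10, "thiram", 1e-5, 1, seed=0)
        neg = make_labeled_set(small_grid, 14, "TBZ", 1e-5, 0, seed=1)
        ds = SpectrumSet.concat([pos, neg])
        out = expand_dataset(ds, AugmentConfig(factor=4, seed=2))
        assert Counter(out.labels) == {1: 40, 0: 56}

    def test_combination_stays_within_stratum(self, raw240):
        out = expand_dataset(raw240, AugmentConfig(factor=6, seed=1))
        key = raw240.meta[["analyte", "concentration_M"]].astype(str).agg("|".join, axis=1)
        combined = out.meta[out.meta["method"] == "combine"]
        assert len(combined) > 0
        for _, row in combined.iterrows():
            parents = [int(p) for p in row["parents"].split(",")]
            assert len({key.iloc[p] for p in parents}) == 1

    def test_singleton_stratum_falls_back(self, small_grid):
        ds = make_labeled_set(small_grid, 1, "thiram", 1e-5, 1, seed=0)
        out = expand_dataset(ds, AugmentConfig(factor=10, seed=0))
        assert len(out) == 10
        assert set(out.meta["method"]) <= {"original", "shift", "noise"}

    def test_deterministic(self, raw240):
        a = expand_dataset(raw240, AugmentConfig(factor=3, seed=5))
        b = expand_dataset(raw240, AugmentConfig(factor=3, seed=5))
        assert np.array_equal(a.X, b.X)


class TestSplit:
    def test_2600_gives_2080_520(self, small_grid):
        pos = make_labeled_set(small_grid, 1300, "thiram", 1e-5, 1, seed=0)
        neg = make_labeled_set(small_grid, 1300, "TBZ", 1e-5, 0, seed=1)
        ds = SpectrumSet.concat([pos, neg])
        tr, va = split_dataset(ds, SplitConfig(train_fraction=0.8, seed=0))
        assert (len(tr), len(va)) == (2080, 520)

    def test_partition_disjoint_exhaustive(self, raw240):
        tr, va = split_dataset(raw240, SplitConfig(train_fraction=0.8, stratified=False, seed=3))
        assert len(tr) + len(va) == len(raw240)
        both = np.vstack([tr.X, va.X])
        assert np.array_equal(np.sort(both, axis=0), np.sort(raw240.X, axis=0))

    def test_stratified_split_balanced(self, small_grid):
        pos = make_labeled_set(small_grid, 50, "thiram", 1e-5, 1, seed=0)
        neg = make_labeled_set(small_grid, 50, "TBZ", 1e-5, 0, seed=1)
        ds = SpectrumSet.concat([pos, neg])
        tr, va = split_dataset(ds, SplitConfig(train_fraction=0.8, stratified=True, seed=0))
        assert abs(int((tr.labels == 1).sum()) - int((tr.labels == 0).sum())) <= 1
        assert abs(int((va.labels == 1).sum()) - int((va.labels == 0).sum())) <= 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.0)

    def test_group_by_parent_blocks_leakage(self, small_grid):
        ds = make_labeled_set(small_grid, 30, "thiram", 1e-5, 1, seed=0)
        out = expand_dataset(ds, AugmentConfig(factor=4, seed=7))
        tr, va = split_dataset(out, SplitConfig(train_fraction=0.8, stratified=False,
                                                seed=1, group_by_parent=True))
        from sersid.augment import _parent_components

        comp = _parent_components(out.meta["parents"])
        tr_comp = {comp[i] for i in range(len(out))
                   if any(np.array_equal(out.X[i], r) for r in tr.X)}
        va_comp = {comp[i] for i in range(len(out))
                   if any(np.array_equal(out.X[i], r) for r in va.X)}
        assert tr_comp.isdisjoint(va_comp)


class TestKFold:
    def test_2600_in_5_folds_of_520(self, small_grid):
        pos = make_labeled_set(small_grid, 1300, "thiram", 1e-5, 1, seed=0)
        neg = make_labeled_set(small_grid, 1300, "TBZ", 1e-5, 0, seed=1)
        ds = SpectrumSet.concat([pos, neg])
        folds = kfold(ds, 5, seed=0)
        assert [f.size for f in folds] == [520] * 5

    def test_folds_partition_dataset(self, raw240):
        folds = kfold(raw240, 7, seed=1)
        allidx = np.concatenate(folds)
        assert np.array_equal(np.sort(allidx), np.arange(len(raw240)))
        assert max(f.size for f in folds) - min(f.size for f in folds) <= 1

    def test_leave_one_out(self, small_grid):
        ds = make_labeled_set(small_grid, 9, "thiram", 1e-5, 1, seed=0)
        folds = kfold(ds, 9, seed=0)
        assert all(f.size == 1 for f in folds)

    def test_k_larger_than_dataset_rejected(self, small_grid):
        ds = make_labeled_set(small_grid, 4, "thiram", 1e-5, 1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            kfold(ds, 5, seed=0)
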