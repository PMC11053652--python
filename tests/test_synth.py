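import numpy as np
import pytest

from sersid.synth import (
    BPE,
    FourPLParams,
    NoiseModel,
    PeakLibrary,
    default_libraries,
    fit_four_pl,
    four_pl,
    generate_blank,
    generate_mixture,
    generate_pure,
)

LIBS = default_libraries()
ZERO = NoiseModel.zero()


class TestFourPL:
    P = FourPLParams(d=20.0, a=1200.0, c=1e-6, b=1.2)

    def test_midpoint_identity(self):
        assert four_pl(self.P.c, self.P) == pytest.approx((self.P.a + self.P.d) / 2)

    def test_upper_asymptote(self):
        assert four_pl(1e3, self.P) == pytest.approx(self.P.a, rel=1e-3)

    def test_zero_concentration_gives_lower_asymptote(self):
        assert four_pl(0.0, self.P) == self.P.d

    @pytest.mark.parametrize("bad", [dict(d=10, a=5, c=1e-6, b=1), dict(d=0, a=1, c=0, b=1)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            FourPLParams(**bad)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            four_pl(-1.0, self.P)

    def test_fit_recovery_from_noisy_titration(self):
        # probe-molecule-style titration spanning both plateaus (the lower
        # asymptote is only identifiable if the curve is sampled down to it)
        true = BPE.response
        rng = np.random.default_rng(42)
        conc = np.logspace(-14, -5, 20)
        amp = four_pl(conc, true)
        amp = amp * (1 + rng.normal(0, 0.02, conc.size))
        fitted, r2 = fit_four_pl(conc, amp)
        assert r2 >= 0.99
        for name in ("d", "a", "c", "b"):
            assert getattr(fitted, name) == pytest.approx(getattr(true, name), rel=0.10)


class TestGeneratePure:
    def test_bpe_peak_positions(self, grid):
        ss = generate_pure(BPE, 1e-6, grid, 1, ZERO, seed=0)
        y = ss.X[0]
        for center in (1198.0, 1605.0, 1636.0):
            i = grid.index_of(center)
            window = y[i - 3 : i + 4]
            local_max = i - 3 + int(np.argmax(window))
            assert abs(local_max - i) <= 1, f"no local maximum near {center}"

    def test_zero_concentration_is_blank_like(self, grid):
        ss = generate_pure(LIBS["thiram"], 0.0, grid, 1, ZERO, seed=0)
        d = LIBS["thiram"].response.d
        # band amplitudes sit at the lower asymptote (tiny tail overlap allowed)
        assert ss.X[0].max() <= 1.01 * d
        assert ss.X[0].min() >= 0.0

    def test_deterministic_given_seed(self, grid):
        a = generate_pure(LIBS["TBZ"], 1e-5, grid, 5, NoiseModel(), seed=11)
        b = generate_pure(LIBS["TBZ"], 1e-5, grid, 5, NoiseModel(), seed=11)
        assert np.array_equal(a.X, b.X)

    def test_zero_noise_non_negative(self, grid):
        for lib in LIBS.values():
            ss = generate_pure(lib, 1e-5, grid, 1, ZERO, seed=0)
            assert ss.X.min() >= 0.0

    def test_amplitude_monotone_in_concentration(self, grid):
        lib = LIBS["CBZ"]
        peaks = [grid.index_of(p.center) for p in lib.peaks]
        heights = [
            generate_pure(lib, c, grid, 1, ZERO, seed=0).X[0][peaks]
            for c in (0.0, 5e-7, 1e-6, 1e-5, 1e-4)
        ]
        for lo, hi in zip(heights, heights[1:]):
            assert np.all(hi >= lo - 1e-9)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            PeakLibrary("empty", ())


class TestGenerateMixture:
    def test_single_component_equals_pure(self, grid):
        noise = NoiseModel()
        mix = generate_mixture([(LIBS["thiram"], 1.0)], 1e-5, grid, 3, noise, seed=5)
        pure = generate_pure(LIBS["thiram"], 1e-5, grid, 3, noise, seed=5)
        assert np.array_equal(mix.X, pure.X)

    def test_fractions_must_sum_to_one(self, grid):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_mixture(
                [(LIBS["thiram"], 0.3), (LIBS["TBZ"], 0.8)], 1e-5, grid, 1, ZERO, seed=0)

    def test_equal_affinity_mixture_is_linear(self, grid):
        comps = [(LIBS["thiram"], 0.05), (LIBS["TBZ"], 0.95)]
        mix = generate_mixture(comps, 1e-5, grid, 1, ZERO, seed=0, affinities=[1.0, 1.0])
        expected = sum(
            frac * generate_pure(lib, 1e-5, grid, 1, ZERO, seed=0).X[0]
            for lib, frac in comps
        )
        assert np.allclose(mix.X[0], expected, rtol=1e-10, atol=1e-10)

    def test_five_percent_component_at_five_percent_amplitude(self, grid):
        # thiram-exclusive band: 1386 cm^-1
        i = grid.index_of(1386.0)
        mix = generate_mixture(
            [(LIBS["thiram"], 0.05), (LIBS["TBZ"], 0.95)], 1e-5, grid, 1, ZERO,
            seed=0, affinities=[1.0, 1.0])
        pure = generate_pure(LIBS["thiram"], 1e-5, grid, 1, ZERO, seed=0)
        # rel 0.1: the majority component's Lorentzian tails also reach 1386
        assert mix.X[0][i] == pytest.approx(0.05 * pure.X[0][i], rel=0.10)

    def test_mixture_labeled_positive_when_thiram_present(self, grid):
        mix = generate_mixture(
            [(LIBS["thiram"], 0.05), (LIBS["TBZ"], 0.475), (LIBS["CBZ"], 0.475)],
            1e-5, grid, 1, ZERO, seed=0)
        assert int(mix.meta["label"].iloc[0]) == 1


class TestGenerateBlank:
    def test_zero_noise_zero_baseline_is_flat(self, grid):
        ss = generate_blank(grid, 2, ZERO, seed=0)
        assert np.all(ss.X == 0.0)

    def test_smooth_baseline_only_when_no_noise(self, grid):
        noise = NoiseModel(additive_sigma=0.0, site_sigma=0.0, baseline_amplitude=150.0)
        y = generate_blank(grid, 1, noise, seed=3).X[0]
        assert y.min() > 0
        # smoothness: second differences tiny relative to the overall scale
        assert np.abs(np.diff(y, 2)).max() < 1e-3 * y.max()

    def test_determinism(self, grid):
        a = generate_blank(grid, 4, NoiseModel(), seed=9)
        b = generate_blank(grid, 4, NoiseModel(), seed=9)
        assert np.array_equal(a.X, b.X)

    def test_pure_separates_from_blank_at_peak_channels(self, grid):
        """Analyte bands stand >= 3 sigma above the blank under default noise."""
        noise = NoiseModel()
        blanks = generate_blank(grid, 30, noise, seed=1)
        for name, lib in default_libraries().items():
            pure = generate_pure(lib, 1e-5, grid, 30, noise, seed=2)
            for p in lib.peaks:
                i = grid.index_of(p.center)
                gap = pure.X[:, i].mean() - blanks.X[:, i].mean()
                assert gap >= 3 * blanks.X[:, i].std(), f"{name} band {p.center}"
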