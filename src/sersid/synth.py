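"""Synthetic SERS spectrum generation.

Emulates the statistical structure of substrate-based SERS measurements of
small-molecule analytes:

* each analyte contributes a set of Lorentzian bands (position, FWHM,
  relative amplitude) — Raman lines are near-Lorentzian;
* band amplitude follows a sigmoidal four-parameter-logistic (4PL)
  concentration–response, the standard dose–response model for
  intensity vs. log-concentration calibration curves;
* mixtures combine components by volume fraction weighted by a per-analyte
  substrate-adsorption affinity (competitive adsorption: strongly binding
  analytes crowd out weak binders, so spectral weight is not proportional
  to volume fraction alone);
* instrument/substrate realism: smooth baseline drift, multiplicative
  site-to-site intensity variability (lognormal), and additive Gaussian noise
  scaled to each spectrum's maximum clean intensity.

The shipped pesticide band positions are literature-plausible placeholders;
only the BPE probe-molecule triplet (1198/1605/1636 cm⁻¹) is anchored to the
characterization literature.  Users supply their own positions via config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import Grid, SpectrumSet

__all__ = [
    "Peak",
    "PeakLibrary",
    "FourPLParams",
    "NoiseModel",
    "four_pl",
    "fit_four_pl",
    "lorentzian",
    "generate_pure",
    "generate_mixture",
    "generate_blank",
    "default_libraries",
    "BPE",
    "DEFAULT_RESPONSE",
]


@dataclass(frozen=True)
class Peak:
    center: float  # cm^-1
    fwhm: float  # cm^-1
    rel_amp: float  # in (0, 1]

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"FWHM must be > 0, got {self.fwhm}")
        if not 0 < self.rel_amp <= 1:
            raise ValueError(f"relative amplitude must be in (0, 1], got {self.rel_amp}")


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic response: lower/upper asymptote, inflection, slope."""

    d: float  # lower asymptote, counts
    a: float  # upper asymptote, counts
    c: float  # inflection concentration, molar
    b: float  # Hill slope, dimensionless

    def __post_init__(self) -> None:
        if self.a <= self.d:
            raise ValueError(f"4PL requires a > d, got a={self.a}, d={self.d}")
        if self.c <= 0:
            raise ValueError(f"4PL requires c > 0, got c={self.c}")


#: Default concentration–response for the pesticide analytes.  The shallow slope
#: places the whole 5e-7 – 1e-4 M working range on the rising flank, so band
#: amplitude spans roughly an order of magnitude across the six concentrations.
DEFAULT_RESPONSE = FourPLParams(d=20.0, a=1200.0, c=1e-4, b=0.5)


@dataclass(frozen=True)
class PeakLibrary:
    """Per-analyte characteristic band set plus its concentration response."""

    name: str
    peaks: tuple[Peak, ...]
    response: FourPLParams = DEFAULT_RESPONSE
    affinity: float = 1.0  # relative substrate-adsorption weight

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"peak library {self.name!r} has no peaks")
        if self.affinity <= 0:
            raise ValueError("affinity must be > 0")

    def signal(self, g: Grid) -> np.ndarray:
        """Unit-response band profile on a grid (before 4PL amplitude scaling)."""
        lo, hi = g.lo, g.hi
        for p in self.peaks:
            if not lo <= p.center <= hi:
                raise ValueError(
                    f"peak at {p.center} cm^-1 outside grid range ({lo}, {hi})"
                )
        x = g.shifts
        y = np.zeros_like(x)
        for p in self.peaks:
            y += p.rel_amp * lorentzian(x, p.center, p.fwhm)
        return y


@dataclass(frozen=True)
class NoiseModel:
    """Noise/variability parameters for the generator.

    additive_sigma — Gaussian noise s.d. as a fraction of each spectrum's
    maximum clean (noise-free) intensity; site_sigma — lognormal s.d. of the
    multiplicative site-to-site enhancement factor (defaults near the 6–8%
    relative standard deviations typical of uniform substrates);
    baseline_amplitude — scale (counts) of the smooth drift; baseline_scale —
    decay scale of its exponential term as a fraction of the spectral range.
    """

    additive_sigma: float = 0.02
    site_sigma: float = 0.07
    baseline_amplitude: float = 150.0
    baseline_scale: float = 0.3

    def __post_init__(self) -> None:
        for name in ("additive_sigma", "site_sigma", "baseline_amplitude", "baseline_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @staticmethod
    def zero() -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, 0.3)


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Lorentzian line profile with unit peak height."""
    gamma = fwhm / 2.0
    return gamma**2 / ((np.asarray(x, float) - center) ** 2 + gamma**2)


def four_pl(concentration, p: FourPLParams):
    """4PL response d + (a - d) / (1 + (c/x)^b); returns d at x = 0 (b > 0 limit)."""
    x = np.asarray(concentration, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.full(x.shape, p.d, dtype=float)
    pos = x > 0
    out[pos] = p.d + (p.a - p.d) / (1.0 + (p.c / x[pos]) ** p.b)
    return float(out[0]) if scalar else out


def fit_four_pl(concentrations: np.ndarray, amplitudes: np.ndarray,
                p0: FourPLParams | None = None) -> tuple[FourPLParams, float]:
    """Least-squares 4PL fit; returns fitted parameters and R²."""
    x = np.asarray(concentrations, float)
    y = np.asarray(amplitudes, float)
    if p0 is None:
        p0 = FourPLParams(
            d=max(float(y.min()), 1e-12),
            a=float(y.max()),
            c=float(np.exp(np.mean(np.log(x[x > 0])))),
            b=1.0,
        )

    # fit on the log-concentration axis: (c/x)^b = 10^(b (log10 c - log10 x)),
    # which keeps the inflection parameter on a well-scaled axis
    lx = np.log10(x)

    def model(lx, d, a, lc, b):
        return d + (a - d) / (1.0 + 10.0 ** (b * (lc - lx)))

    # 1/y weighting: SERS calibration noise is close to constant-CV, so an
    # unweighted fit would let the large-amplitude plateau swamp the lower asymptote
    popt, _ = curve_fit(
        model, lx, y, p0=[p0.d, p0.a, np.log10(p0.c), p0.b],
        sigma=np.maximum(np.abs(y), 1e-12 * max(1.0, float(np.abs(y).max()))),
        bounds=([-np.inf, 0, -300, 1e-3], [np.inf, np.inf, 300, 100]),
        maxfev=20000,
    )
    fitted = FourPLParams(d=popt[0], a=popt[1], c=10.0 ** popt[2], b=popt[3])
    resid = y - model(lx, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return fitted, r2


def _baseline(g: Grid, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """One realization of smooth drift: exponential decay + low-order polynomial."""
    t = (g.shifts - g.lo) / (g.hi - g.lo)
    c_exp = rng.uniform(0.3, 1.0)
    c_lin = rng.uniform(0.0, 0.5)
    c_quad = rng.uniform(0.0, 0.5)
    shape = 0.1 + c_exp * np.exp(-t / max(noise.baseline_scale, 1e-6)) + c_lin * t + c_quad * t**2
    return noise.baseline_amplitude * shape


def _assemble(signal: np.ndarray, g: Grid, n: int, noise: NoiseModel,
              rng: np.random.Generator, meta_row: dict) -> SpectrumSet:
    """Stack n realizations of baseline + site-factor × signal + additive noise."""
    X = np.empty((n, g.n))
    for i in range(n):
        base = _baseline(g, noise, rng)
        site = rng.lognormal(0.0, noise.site_sigma) if noise.site_sigma > 0 else 1.0
        clean = base + site * signal
        sigma = noise.additive_sigma * float(clean.max()) if clean.max() > 0 else 0.0
        X[i] = clean + (rng.normal(0.0, sigma, g.n) if sigma > 0 else 0.0)
    meta = pd.DataFrame([dict(meta_row)] * n)
    return SpectrumSet(g.shifts, X, meta)


def generate_pure(analyte: PeakLibrary, concentration: float, g: Grid, n: int,
                  noise: NoiseModel, seed: int) -> SpectrumSet:
    """Generate n spectra of a single analyte at one concentration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    amp = four_pl(concentration, analyte.response)
    signal = amp * analyte.signal(g)
    meta = {
        "analyte": analyte.name,
        "concentration_M": concentration,
        "label": int(analyte.name == "thiram"),
        "provenance": "synthetic",
    }
    return _assemble(signal, g, n, noise, rng, meta)


def generate_mixture(components: Sequence[tuple[PeakLibrary, float]],
                     concentration: float, g: Grid, n: int, noise: NoiseModel,
                     seed: int,
                     affinities: Sequence[float] | None = None) -> SpectrumSet:
    """Generate spectra of a volume-ratio mixture of analyte stock solutions.

    Each component's spectral weight is proportional to volume-fraction ×
    adsorption affinity, renormalized to sum to 1 (competitive adsorption).
    ``affinities=None`` uses each library's own affinity attribute; pass equal
    values for ideal (purely linear) mixing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    libs = [c[0] for c in components]
    fracs = np.array([c[1] for c in components], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("volume fractions must be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {fracs.sum()!r}")
    if affinities is None:
        aff = np.array([lib.affinity for lib in libs], dtype=float)
    else:
        aff = np.asarray(affinities, dtype=float)
    if aff.shape != fracs.shape or np.any(aff <= 0):
        raise ValueError("affinities must be positive, one per component")
    w = fracs * aff
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    signal = np.zeros(g.n)
    for lib, wi in zip(libs, w):
        signal += wi * four_pl(concentration, lib.response) * lib.signal(g)
    names = "+".join(lib.name for lib in libs)
    meta = {
        "analyte": names,
        "concentration_M": concentration,
        "label": int(any(lib.name == "thiram" and f > 0 for lib, f in components)),
        "provenance": "synthetic",
    }
    return _assemble(signal, g, n, noise, rng, meta)


def generate_blank(g: Grid, n: int, noise: NoiseModel, seed: int) -> SpectrumSet:
    """Substrate/solvent-only spectra: smooth baseline plus noise, no analyte bands."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    meta = {
        "analyte": "substrate",
        "concentration_M": 0.0,
        "label": 0,
        "provenance": "synthetic",
    }
    return _assemble(np.zeros(g.n), g, n, noise, rng, meta)


#: Probe molecule used for substrate characterization; band positions from the
#: characterization literature (C=C stretch, aromatic ring stretch, in-plane ring).
BPE = PeakLibrary(
    "BPE",
    (
        Peak(1198.0, 12.0, 1.0),
        Peak(1605.0, 12.0, 0.85),
        Peak(1636.0, 12.0, 0.90),
    ),
    response=FourPLParams(d=15.0, a=2000.0, c=1e-9, b=0.8),
)


def default_libraries() -> dict[str, PeakLibrary]:
    """Shipped placeholder band sets for the four pesticide analytes.

    Bands are distinct per analyte except two shared "aromatic" bands
    (1001 and 1576 cm⁻¹) that overlap between the negative-class analytes,
    emulating band overlap in multi-analyte samples.  Thiram (the positive
    class) gets a high adsorption affinity: its dithiocarbamate sulfurs bind
    gold strongly, which is what keeps a 5%-volume-fraction component visible
    in mixture spectra under competitive adsorption.
    """
    w = 12.0
    return {
        "thiram": PeakLibrary(
            "thiram",
            (
                Peak(560.0, w, 0.45),
                Peak(928.0, w, 0.35),
                Peak(1146.0, w, 0.60),
                Peak(1386.0, w, 1.00),
                Peak(1512.0, w, 0.50),
            ),
            affinity=8.0,
        ),
        "TBZ": PeakLibrary(
            "TBZ",
            (
                Peak(782.0, w, 0.90),
                Peak(878.0, w, 0.35),
                Peak(1001.0, w, 0.60),
                Peak(1273.0, w, 0.75),
                Peak(1576.0, w, 0.55),
            ),
            affinity=1.0,
        ),
        "CBZ": PeakLibrary(
            "CBZ",
            (
                Peak(633.0, w, 0.40),
                Peak(1001.0, w, 0.70),
                Peak(1227.0, w, 0.80),
                Peak(1315.0, w, 0.50),
                Peak(1576.0, w, 0.60),
            ),
            affinity=1.0,
        ),
        "phosmet": PeakLibrary(
            "phosmet",
            (
                Peak(607.0, w, 0.50),
                Peak(655.0, w, 0.60),
                Peak(715.0, w, 0.40),
                Peak(1193.0, w, 0.80),
                Peak(1417.0, w, 0.60),
            ),
            affinity=1.5,
        ),
    }
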