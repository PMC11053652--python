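"""Baseline correction (airPLS) and normalization.

airPLS — adaptive iteratively reweighted penalized least squares — estimates a
smooth baseline with a Whittaker smoother whose weights are re-derived each
iteration from the sign and size of the residuals: channels above the current
baseline (candidate peaks) get zero weight, channels below get exponentially
increasing weight, so the fit relaxes onto the peak-free background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .io import Spectrum, SpectrumSet

__all__ = ["PreprocessConfig", "airpls_baseline", "correct", "correct_set", "normalize"]

_NORM_METHODS = ("none", "minmax", "vector")


@dataclass(frozen=True)
class PreprocessConfig:
    """airPLS smoothness penalty + iteration budget, and the normalization method."""

    lam: float = 1e4
    max_iter: int = 15
    ratio: float = 0.001
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.ratio < 1:
            raise ValueError("convergence ratio must be in (0, 1)")
        if self.normalization not in _NORM_METHODS:
            raise ValueError(f"normalization must be one of {_NORM_METHODS}")


def _penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form (bandwidth 2) of lam * D'D for the second-difference D."""
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    A = (lam * (D.T @ D)).todia()
    ab = np.zeros((3, n))
    for off, data in zip(A.offsets, A.data):
        if off == 0:
            ab[2] = data
        elif off == 1:
            ab[1] = data
        elif off == 2:
            ab[0] = data
    return ab


def _whittaker(y: np.ndarray, w: np.ndarray, ab_penalty: np.ndarray) -> np.ndarray:
    ab = ab_penalty.copy()
    ab[2] += w
    return solveh_banded(ab, w * y, lower=False)


def airpls_baseline(y: np.ndarray, cfg: PreprocessConfig = PreprocessConfig(),
                    _ab_penalty: np.ndarray | None = None) -> np.ndarray:
    """Estimate the smooth baseline of one intensity vector.

    Iterates the reweighted Whittaker smoother until the mass of negative
    residuals drops below ``ratio`` × total absolute intensity, or the
    iteration budget is exhausted.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("airPLS needs a 1-D vector of length >= 8")
    if not np.all(np.isfinite(y)):
        raise ValueError("airPLS input must be finite")
    n = y.size
    ab = _penalty_bands(n, cfg.lam) if _ab_penalty is None else _ab_penalty
    abs_sum = np.abs(y).sum()
    w = np.ones(n)
    z = y.copy()
    for it in range(1, cfg.max_iter + 1):
        z = _whittaker(y, w, ab)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn == 0.0 or dssn < cfg.ratio * abs_sum:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        # anchor the endpoints so the smoother stays attached to the spectrum edges
        edge = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[0] = edge
        w[-1] = edge
    return z


def correct(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Subtract the airPLS baseline; negative residual intensities are kept."""
    z = airpls_baseline(s.intensities, cfg)
    meta = dict(s.meta)
    meta["baseline"] = "airpls"
    return Spectrum(s.shifts.copy(), s.intensities - z, meta)


def correct_set(ss: SpectrumSet, cfg: PreprocessConfig = PreprocessConfig()) -> SpectrumSet:
    """airPLS-correct every spectrum in a set (shared penalty factorization setup)."""
    n = ss.X.shape[1]
    ab = _penalty_bands(n, cfg.lam)
    X = np.empty_like(ss.X)
    for i in range(ss.X.shape[0]):
        X[i] = ss.X[i] - airpls_baseline(ss.X[i], cfg, _ab_penalty=ab)
    meta = ss.meta.copy()
    meta["baseline"] = "airpls"
    return SpectrumSet(ss.shifts, X, meta)


def normalize(s: Spectrum, method: str = "minmax") -> Spectrum:
    """Per-spectrum normalization: min-max to [0, 1], unit Euclidean norm, or identity."""
    if method not in _NORM_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "none":
        return s.copy()
    y = s.intensities
    if method == "minmax":
        rng = float(y.max() - y.min())
        if rng == 0.0:
            raise ValueError("min-max normalization undefined for a constant spectrum")
        out = (y - y.min()) / rng
    else:  # vector
        nrm = float(np.linalg.norm(y))
        if nrm == 0.0:
            raise ValueError("vector normalization undefined for an all-zero spectrum")
        out = y / nrm
    meta = dict(s.meta)
    meta["normalized"] = method
    return Spectrum(s.shifts.copy(), out, meta)


def normalize_matrix(X: np.ndarray, method: str) -> np.ndarray:
    """Row-wise normalization of an intensity matrix (same methods as normalize)."""
    if method not in _NORM_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    X = np.asarray(X, dtype=float)
    if method == "none":
        return X.copy()
    if method == "minmax":
        lo = X.min(axis=1, keepdims=True)
        rng = X.max(axis=1, keepdims=True) - lo
        if np.any(rng == 0):
            raise ValueError("min-max normalization undefined for a constant spectrum")
        return (X - lo) / rng
    nrm = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("vector normalization undefined for an all-zero spectrum")
    return X / nrm
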