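"""Reading, writing, validation and regridding of Raman/SERS spectra.

A spectrum is stored on disk as plain two-column text (``shift_cm1,intensity``,
comma- or tab-separated, with optional ``#``-prefixed header lines carrying
``key=value`` metadata).  A dataset is a directory of such files plus one TSV
manifest.  Every other module goes through the containers defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Grid",
    "SpectrumSet",
    "DEFAULT_GRID",
    "MANIFEST_COLUMNS",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "read_manifest",
    "write_manifest",
]

#: Manifest schema (TSV, tab-separated, with header).
MANIFEST_COLUMNS = ["path", "analyte", "concentration_M", "label", "provenance"]

_PROVENANCES = {"raw", "augmented", "synthetic"}


class SpectrumError(ValueError):
    """Malformed spectrum file or invalid spectrum data."""


@dataclass(frozen=True)
class Grid:
    """A uniform Raman-shift axis: ``n`` channels from ``lo`` to ``hi`` cm⁻¹ inclusive."""

    lo: float = 400.0
    hi: float = 1800.0
    n: int = 900

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"grid requires lo < hi, got ({self.lo}, {self.hi})")
        if self.n < 2:
            raise ValueError(f"grid requires n >= 2, got {self.n}")

    @property
    def shifts(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)

    def index_of(self, shift_cm1: float) -> int:
        """Nearest channel index for a Raman shift."""
        return int(np.argmin(np.abs(self.shifts - shift_cm1)))


#: 400–1800 cm⁻¹ over 900 channels (≈1.557 cm⁻¹ spacing), the pipeline default.
DEFAULT_GRID = Grid(400.0, 1800.0, 900)


@dataclass
class Spectrum:
    """One Raman trace: strictly increasing shift axis + finite intensity vector."""

    shifts: np.ndarray
    intensities: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumError("shifts and intensities must be 1-D")
        if self.shifts.size != self.intensities.size:
            raise SpectrumError(
                f"length mismatch: {self.shifts.size} shifts vs "
                f"{self.intensities.size} intensities"
            )
        if self.shifts.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        order = np.argsort(self.shifts, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.shifts = self.shifts[order]
            self.intensities = self.intensities[order]
        if np.any(np.diff(self.shifts) <= 0):
            raise SpectrumError("shifts contain duplicates; axis must be strictly increasing")
        if not np.all(np.isfinite(self.shifts)) or not np.all(np.isfinite(self.intensities)):
            raise SpectrumError("non-finite values in spectrum")

    def __len__(self) -> int:
        return int(self.shifts.size)

    def copy(self) -> "Spectrum":
        return Spectrum(self.shifts.copy(), self.intensities.copy(), dict(self.meta))


class SpectrumSet:
    """A labeled collection of spectra sharing one grid.

    Thin wrapper over an ``(n_spectra, n_channels)`` intensity matrix plus a
    :class:`pandas.DataFrame` of per-spectrum metadata (analyte, concentration_M,
    label, provenance, ...).  Row ``i`` of ``X`` and of ``meta`` describe the
    same spectrum.
    """

    def __init__(self, shifts: np.ndarray, X: np.ndarray, meta: pd.DataFrame):
        shifts = np.asarray(shifts, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != shifts.size:
            raise ValueError(f"X shape {X.shape} does not match {shifts.size} channels")
        if len(meta) != X.shape[0]:
            raise ValueError("meta rows must match spectra count")
        self.shifts = shifts
        self.X = X
        self.meta = meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def spectrum(self, i: int) -> Spectrum:
        meta = {k: str(v) for k, v in self.meta.iloc[i].items()}
        return Spectrum(self.shifts.copy(), self.X[i].copy(), meta)

    def subset(self, idx) -> "SpectrumSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(self.shifts, self.X[idx], self.meta.iloc[idx])

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=int)

    @staticmethod
    def concat(sets: list["SpectrumSet"]) -> "SpectrumSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        shifts = sets[0].shifts
        for s in sets[1:]:
            if not np.array_equal(s.shifts, shifts):
                raise ValueError("grids differ between sets")
        X = np.vstack([s.X for s in sets])
        meta = pd.concat([s.meta for s in sets], ignore_index=True)
        return SpectrumSet(shifts, X, meta)

    @staticmethod
    def from_spectra(spectra: list[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("empty spectrum list")
        shifts = spectra[0].shifts
        for s in spectra[1:]:
            if not np.array_equal(s.shifts, shifts):
                raise ValueError("grids differ between spectra")
        X = np.vstack([s.intensities for s in spectra])
        meta = pd.DataFrame([s.meta for s in spectra])
        return SpectrumSet(shifts, X, meta)


_NUM = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column text spectrum.

    Accepts comma or tab separation and ``#``-prefixed header lines; a header
    line of the form ``# key=value`` is parsed into ``Spectrum.meta``.
    Descending shift order is normalized to ascending.

    Raises :class:`SpectrumError` naming the offending line for malformed rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    shifts: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = [p for p in re.split(r"[,\t]", line) if p.strip() != ""]
            if len(parts) != 2 or not all(_NUM.match(p.strip()) for p in parts):
                raise SpectrumError(f"{path}: malformed row at line {lineno}: {line!r}")
            shifts.append(float(parts[0]))
            intens.append(float(parts[1]))
    if len(shifts) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data rows")
    return Spectrum(np.array(shifts), np.array(intens), meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as ``shift_cm1,intensity`` CSV with metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in s.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# shift_cm1,intensity\n")
        for x, y in zip(s.shifts, s.intensities):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def resample(s: Spectrum, g: Grid) -> Spectrum:
    """Linear interpolation of a spectrum onto a grid; no extrapolation.

    Raises ``ValueError`` if the grid extends beyond the spectrum's support —
    extrapolated intensities would be invented data.
    """
    eps = 1e-9
    if g.lo < s.shifts[0] - eps or g.hi > s.shifts[-1] + eps:
        raise ValueError(
            f"grid ({g.lo}, {g.hi}) exceeds spectrum support "
            f"({s.shifts[0]}, {s.shifts[-1]}); extrapolation is not supported"
        )
    new = np.interp(g.shifts, s.shifts, s.intensities)
    return Spectrum(g.shifts, new, dict(s.meta))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV dataset manifest."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    _validate_manifest(df)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    _validate_manifest(df)
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def _validate_manifest(df: pd.DataFrame) -> None:
    if not df["label"].isin([0, 1]).all():
        raise ValueError("manifest labels must be 0 or 1")
    if (df["concentration_M"].astype(float) < 0).any():
        raise ValueError("manifest concentrations must be >= 0")
    bad = set(df["provenance"]) - _PROVENANCES
    if bad:
        raise ValueError(f"unknown provenance values: {sorted(bad)}")


def load_spectra(manifest: pd.DataFrame, root: str | Path, grid: Grid | None = None) -> SpectrumSet:
    """Load every spectrum in a manifest (paths relative to ``root``) onto one grid."""
    root = Path(root)
    spectra = []
    for _, row in manifest.iterrows():
        s = read_spectrum(root / row["path"])
        if grid is not None:
            s = resample(s, grid)
        s.meta.update(
            analyte=str(row["analyte"]),
            concentration_M=str(row["concentration_M"]),
            label=str(int(row["label"])),
            provenance=str(row["provenance"]),
        )
        spectra.append(s)
    ss = SpectrumSet.from_spectra(spectra)
    ss.meta["label"] = ss.meta["label"].astype(int)
    ss.meta["concentration_M"] = ss.meta["concentration_M"].astype(float)
    return ss
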