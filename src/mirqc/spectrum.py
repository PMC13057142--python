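"""Spectrum container and basic spectral operations.

A :class:`Spectrum` is a single mid-infrared spectrum: a strictly increasing
wavenumber grid (cm^-1) paired with intensity values, plus a measurement mode
(``absorbance``, ``transmission`` or ``ratio``) and free-form metadata.
Spectra are read from and written to plain CSV in two dialects:

``wide``
    first column is the wavenumber, every further column one spectrum
    (column name = spectrum id);
``long``
    three columns ``id``, ``wavenumber``, ``intensity``.

Operations here are the generic plumbing every quality-control step builds
on: interpolation onto a regular grid, clipping to a wavenumber interval,
transmission-to-absorbance conversion, and nearest-grid-point intensity
lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyRegionError,
    OutOfRangeError,
    ParseError,
)

MODES = ("absorbance", "transmission", "ratio")

#: transmission values below this are clamped before taking the logarithm
TRANSMISSION_FLOOR = 1e-8


@dataclass
class Spectrum:
    """One spectrum: wavenumber grid, intensities, mode, metadata."""

    id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    mode: str = "absorbance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValueError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(w)):
            raise ValueError("wavenumbers must be finite")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.any(np.isinf(y)):
            raise ValueError("intensities must be finite or NaN (missing)")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        self.wavenumbers = w
        self.intensities = y

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def wmin(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def wmax(self) -> float:
        return float(self.wavenumbers[-1])

    def covers(self, a: float, b: float) -> bool:
        """Whether the closed interval [a, b] lies within the spectral range."""
        return self.wmin <= a and b <= self.wmax

    def with_intensities(self, y: np.ndarray, **changes) -> "Spectrum":
        """Copy of this spectrum with new intensities (same grid)."""
        return replace(self, intensities=np.asarray(y, dtype=float), **changes)


@dataclass
class SpectraBatch:
    """An ordered collection of spectra."""

    spectra: list

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def shared_grid(self) -> bool:
        """True when all member spectra sit on the identical wavenumber grid."""
        if not self.spectra:
            return True
        w0 = self.spectra[0].wavenumbers
        return all(np.array_equal(s.wavenumbers, w0) for s in self.spectra[1:])

    def map(self, fn) -> "SpectraBatch":
        return SpectraBatch([fn(s) for s in self.spectra])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _numeric_column(df: pd.DataFrame, col: str) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {raw.iloc[row]!r} in column {col!r} at data row {row}"
        )
    return vals.to_numpy(dtype=float)


def read_spectra(path, dialect: str = "wide", mode: str = "absorbance") -> SpectraBatch:
    """Read spectra from a CSV file.

    Parameters
    ----------
    path : str or Path
        CSV file to read.
    dialect : {"wide", "long"}
        Column layout, see module docstring.
    mode : str
        Measurement mode assigned to every spectrum (CSV carries none).
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if dialect == "wide":
        if df.shape[1] < 2:
            raise ParseError(
                f"wide CSV needs a wavenumber column plus >= 1 spectrum column, "
                f"got columns {list(df.columns)}"
            )
        wcol = df.columns[0]
        w = _numeric_column(df, wcol)
        order = np.argsort(w, kind="stable")
        spectra = []
        for col in df.columns[1:]:
            y = _numeric_column(df, col)[order]
            spectra.append(Spectrum(str(col), w[order], y, mode=mode))
        return SpectraBatch(spectra)
    # long
    required = ("id", "wavenumber", "intensity")
    for col in required:
        if col not in df.columns:
            raise ParseError(
                f"long CSV is missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    spectra = []
    for sid in df["id"].drop_duplicates():
        sub = df[df["id"] == sid]
        w = _numeric_column(sub.reset_index(drop=True), "wavenumber")
        y = _numeric_column(sub.reset_index(drop=True), "intensity")
        order = np.argsort(w, kind="stable")
        spectra.append(Spectrum(str(sid), w[order], y[order], mode=mode))
    return SpectraBatch(spectra)


def write_spectra(batch, path, dialect: str = "wide", float_format=None) -> None:
    """Write spectra to CSV (UTF-8, '.' decimal, ',' separator).

    The wide dialect requires all spectra to share one grid.  Full float
    precision is kept unless ``float_format`` is given.
    """
    spectra = list(batch)
    if dialect == "wide":
        if not spectra:
            pd.DataFrame({"wavenumber": []}).to_csv(path, index=False)
            return
        b = SpectraBatch(spectra)
        if not b.shared_grid:
            raise ValueError("wide CSV output requires a shared wavenumber grid")
        data = {"wavenumber": spectra[0].wavenumbers}
        for s in spectra:
            data[s.id] = s.intensities
        pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {"id": s.id, "wavenumber": s.wavenumbers, "intensity": s.intensities}
            )
            for s in spectra
        ]
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["id", "wavenumber", "intensity"])
        )
        out.to_csv(path, index=False, float_format=float_format)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------


def interpolate_to_grid(s: Spectrum, dw: float = 1.0) -> Spectrum:
    """Linearly interpolate a spectrum onto a regular grid of spacing ``dw``.

    For ``dw = 1`` the output grid is the consecutive integers from
    ``ceil(min wavenumber)`` to ``floor(max wavenumber)``; no extrapolation is
    performed.  Missing (NaN) intensities inside the spectrum are bridged
    linearly; leading/trailing missing points are dropped.
    """
    if dw <= 0:
        raise ValueError(f"dw must be > 0, got {dw}")
    finite = np.isfinite(s.intensities)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing points to interpolate")
    w = s.wavenumbers[finite]
    y = s.intensities[finite]
    n0 = math.ceil(w[0] / dw - 1e-9)
    n1 = math.floor(w[-1] / dw + 1e-9)
    if n1 < n0:
        raise EmptyRegionError(
            f"no grid points with spacing {dw} inside [{w[0]}, {w[-1]}]"
        )
    grid = np.arange(n0, n1 + 1, dtype=float) * dw
    out = np.interp(grid, w, y)
    return s.with_intensities(out, wavenumbers=grid)


def clip(s: Spectrum, a: float, b: float) -> Spectrum:
    """Retain exactly the grid points with ``a <= wavenumber <= b``."""
    if not a < b:
        raise ValueError(f"invalid interval [{a}, {b}]")
    mask = (s.wavenumbers >= a) & (s.wavenumbers <= b)
    if not mask.any():
        raise EmptyRegionError(
            f"[{a}, {b}] does not overlap spectrum range "
            f"[{s.wmin}, {s.wmax}] for {s.id!r}"
        )
    return s.with_intensities(s.intensities[mask], wavenumbers=s.wavenumbers[mask])


def to_absorbance(s: Spectrum, clamp: bool = True) -> Spectrum:
    """Convert transmission (or ratio) intensities to absorbance, A = -log10 T.

    Transmission values below :data:`TRANSMISSION_FLOOR` are clamped before
    the logarithm unless ``clamp`` is disabled, in which case non-positive
    values raise :class:`~mirqc.errors.DomainError`.
    """
    if s.mode == "absorbance":
        raise ValueError("spectrum is already in absorbance mode")
    t = s.intensities
    if clamp:
        t = np.maximum(t, TRANSMISSION_FLOOR)
    elif np.any(t[np.isfinite(t)] <= 0):
        raise DomainError("non-positive transmission values with clamping disabled")
    with np.errstate(invalid="ignore"):
        a = -np.log10(t)
    return s.with_intensities(a, mode="absorbance")


def nearest_index(s: Spectrum, nu: float) -> int:
    """Index of the grid point nearest ``nu``; ties break toward lower wavenumber."""
    w = s.wavenumbers
    if nu < w[0] or nu > w[-1]:
        raise OutOfRangeError(
            f"wavenumber {nu} outside spectrum range [{w[0]}, {w[-1]}] for {s.id!r}"
        )
    i = int(np.searchsorted(w, nu))
    if i == 0:
        return 0
    if i == w.size:
        return int(w.size - 1)
    # tie (equal distances) goes to the lower wavenumber
    return i - 1 if (nu - w[i - 1]) <= (w[i] - nu) else i


def intensity_at(s: Spectrum, nu: float) -> float:
    """Intensity at the grid point nearest ``nu`` (ties toward lower wavenumber)."""
    return float(s.intensities[nearest_index(s, nu)])
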