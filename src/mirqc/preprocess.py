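"""Spectral preprocessing: baselines, region replacement, normalisation.

The central primitive is the rubberband baseline: the lower convex hull of
the (wavenumber, intensity) point set, interpolated piecewise-linearly
between hull vertices and subtracted from the spectrum.  It removes any
affine (offset + slope) baseline exactly and smooth convex drift
approximately, which is why the total-area statistic built on it is
baseline-invariant.

``total_area`` is the normaliser A for all relative QC indicators: the sum
of intensities after clipping to the area range, linearly bridging the CO2
doublet region (negative CO2 artifacts would otherwise corrupt the hull),
and rubberband correction.

``extract_peak`` isolates an atmospheric-artifact region while preserving
the artifact's sign: a comb of gas lines can point up (more gas during the
sample scan than the background scan) or down (less), and the hull is taken
on the flipped region in the latter case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .config import QCConfig
from .errors import CoverageError, DegenerateSpectrumError
from .spectrum import Spectrum, clip, intensity_at, nearest_index


@dataclass
class PreprocessResult:
    """Outcome of a baseline-type step: primary spectrum + optional baseline."""

    spectrum: Spectrum
    baseline: Spectrum = None
    steps: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rubberband (lower convex hull) baseline
# ---------------------------------------------------------------------------


def lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vertex indices of the lower convex hull of points sorted by x.

    Andrew's monotone chain restricted to the lower chain; collinear interior
    points are dropped, so the first and last point are always vertices.
    """
    n = x.size
    hull: list = []
    for i in range(n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # cross product (k - j) x (i - j); <= 0 means k is not a strict
            # downward vertex between j and i
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=np.intp)


def rubberband(s: Spectrum, return_baseline: bool = False) -> PreprocessResult:
    """Rubberband baseline correction via the lower convex hull.

    Returns a :class:`PreprocessResult` whose ``baseline`` is always the
    piecewise-linear hull baseline; ``spectrum`` is the corrected spectrum,
    or the baseline itself when ``return_baseline`` is set.
    """
    if len(s) < 3:
        raise ValueError("rubberband needs at least 3 points")
    if not np.all(np.isfinite(s.intensities)):
        raise ValueError("rubberband needs finite intensities")
    idx = lower_hull_indices(s.wavenumbers, s.intensities)
    baseline = np.interp(
        s.wavenumbers, s.wavenumbers[idx], s.intensities[idx]
    )
    corrected = s.intensities - baseline
    base_s = s.with_intensities(baseline, id=f"{s.id}::baseline")
    corr_s = s.with_intensities(corrected)
    return PreprocessResult(
        spectrum=base_s if return_baseline else corr_s,
        baseline=base_s,
        steps=["rubberband"],
    )


def replace_region_linear(s: Spectrum, a: float, b: float) -> Spectrum:
    """Replace intensities strictly inside [a, b] by the chord between the
    boundary grid points (the first point >= a and the last point <= b)."""
    w = s.wavenumbers
    inside = np.flatnonzero((w >= a) & (w <= b))
    if inside.size < 3:
        raise ValueError(f"region [{a}, {b}] contains fewer than 3 grid points")
    lo, hi = int(inside[0]), int(inside[-1])
    if lo == 0 or hi == w.size - 1:
        raise ValueError(
            f"region [{a}, {b}] touches the spectrum boundary; no anchor point"
        )
    y = s.intensities.copy()
    y[lo + 1 : hi] = y[lo] + (y[hi] - y[lo]) * (w[lo + 1 : hi] - w[lo]) / (
        w[hi] - w[lo]
    )
    return s.with_intensities(y)


def chord_fill(y: np.ndarray, w: np.ndarray, lo: int, hi: int) -> None:
    """In-place: set y strictly between indices lo and hi onto the chord."""
    y[lo + 1 : hi] = y[lo] + (y[hi] - y[lo]) * (w[lo + 1 : hi] - w[lo]) / (w[hi] - w[lo])


def savgol_residual(s: Spectrum, window: int, order: int) -> Spectrum:
    """Spectrum minus its Savitzky-Golay smooth: the noise component."""
    if window % 2 == 0 or window <= order:
        raise ValueError(f"window must be odd and > order (got {window}, {order})")
    if window > len(s):
        raise ValueError(f"window {window} exceeds spectrum length {len(s)}")
    smooth = savgol_filter(s.intensities, window, order, mode="interp")
    return s.with_intensities(s.intensities - smooth)


def normalize(s: Spectrum, method: str = "sum", anchor: float = None) -> Spectrum:
    """Normalise intensities.

    ``area``/``sum`` divide by the sum of all intensities; ``at_wavenumber``
    divides by the intensity at the grid point nearest ``anchor``.
    """
    if method in ("area", "sum"):
        denom = float(np.sum(s.intensities))
    elif method == "at_wavenumber":
        if anchor is None:
            raise ValueError("at_wavenumber normalisation needs an anchor")
        denom = intensity_at(s, anchor)
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    if denom == 0 or not np.isfinite(denom):
        raise DegenerateSpectrumError(
            f"normaliser is {denom} for spectrum {s.id!r}"
        )
    return s.with_intensities(s.intensities / denom)


# ---------------------------------------------------------------------------
# Total-area statistic and signed peak-region extraction
# ---------------------------------------------------------------------------


def area_pipeline(s: Spectrum, cfg: QCConfig = None) -> PreprocessResult:
    """Clip to the area range, bridge the CO2 region, rubberband-correct.

    Returns corrected spectrum + baseline; the sum of the corrected
    intensities is the total-area statistic A.
    """
    cfg = cfg or QCConfig()
    a, b = cfg.area_range
    if not s.covers(a, b):
        raise CoverageError(
            f"spectrum {s.id!r} covers [{s.wmin}, {s.wmax}], "
            f"missing part of the area range [{a}, {b}]"
        )
    clipped = clip(s, a, b)
    bridged = replace_region_linear(clipped, *cfg.co2_interp_range)
    res = rubberband(bridged)
    res.steps = ["clip", "co2_bridge", "rubberband"]
    return res


def total_area(s: Spectrum, cfg: QCConfig = None) -> float:
    """Total baseline-corrected spectral area A over the area range."""
    corrected = area_pipeline(s, cfg).spectrum
    return float(np.sum(corrected.intensities))


def extract_peak(s: Spectrum, a: float, b: float, peak_max: float) -> Spectrum:
    """Clip to [a, b] and rubberband-correct, preserving the artifact sign.

    The sign is decided at the single grid point nearest ``peak_max``: if its
    intensity lies below the chord joining the region's endpoint intensities
    the artifact is negative, and the hull is taken on the negated region so
    the output keeps its downward orientation.  Output endpoints are 0 and
    all values share one sign for pure-artifact regions.
    """
    region = clip(s, a, b)
    if len(region) < 3:
        raise ValueError(f"region [{a}, {b}] has fewer than 3 points")
    w, y = region.wavenumbers, region.intensities
    i = nearest_index(region, peak_max)
    chord = y[0] + (y[-1] - y[0]) * (w[i] - w[0]) / (w[-1] - w[0])
    negative = y[i] < chord  # ties count as positive
    if negative:
        flipped = region.with_intensities(-y)
        out = rubberband(flipped).spectrum
        return out.with_intensities(-out.intensities, id=s.id)
    out = rubberband(region).spectrum
    return out.with_intensities(out.intensities, id=s.id)
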