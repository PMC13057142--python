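"""Quality indicators for mid-infrared spectra.

Four indicators are computed per spectrum, all normalised by the total
baseline-corrected area A so they are comparable across instruments and
sample amounts:

* **baseline detector** — the rubberband baseline of the spectrum, clipped
  to [1400, 3400] cm^-1 and divided by A, evaluated at 1400 cm^-1 (i1400).
  Organic-matter spectra that were not baseline corrected carry large
  baseline absorbance at low wavenumbers, so i1400 above the threshold t_bc
  marks a spectrum as *not* baseline corrected.
* **water-vapor contribution** c_wv — the OLS slope (with intercept) of the
  spectrum's area-normalised [3780, 3920] cm^-1 artifact region on the same
  region of the water-vapor reference.  c = 1 when the query *is* the
  reference; c ~ 0 for clean spectra; c < 0 for negative artifacts.
* **CO2 contribution** c_co2 — same construction over [2250, 2450] cm^-1
  against the CO2 reference.
* **noise level** c_noise — the variance of the Savitzky-Golay residual
  (normalised by the spectral sum) in the peak-free window
  [2700, 2750] cm^-1.

The batch report uses the column names of the database table these
indicators are stored in (``mir_water_vapor_contribution_relative`` etc.).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCConfig
from .errors import CoverageError, DegenerateSpectrumError, FitError, MirqcError
from .preprocess import (
    area_pipeline,
    extract_peak,
    savgol_residual,
)
from .reference import ReferenceSpectrum
from .spectrum import Spectrum, clip, intensity_at

logger = logging.getLogger(__name__)

#: fixed column order of the QC report
REPORT_COLUMNS = [
    "id",
    "is_baseline_corrected",
    "mir_water_vapor_contribution_relative",
    "mir_water_vapor_contribution_relative_sd",
    "mir_co2_contribution_relative",
    "mir_co2_contribution_relative_sd",
    "noise_level_relative",
    "i1400",
    "total_area",
    "flags",
]


def linear_fit(x: np.ndarray, y: np.ndarray):
    """Two-parameter OLS fit of y on x: (slope, slope standard error).

    Closed-form centred formulas.  When ``y`` is bitwise identical to ``x``
    the slope is exactly 1.0 and the standard error exactly 0.0, which the
    self-calibration identity of the artifact estimators relies on.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise FitError("need at least 3 points for a slope standard error")
    dx = x - x.mean()
    sxx = float(np.sum(dx * dx))
    if sxx == 0:
        raise FitError("regressor has zero variance")
    slope = float(np.sum(dx * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid * resid))
    se = math.sqrt(ssr / (n - 2) / sxx)
    return slope, se


@dataclass
class QCRecord:
    """Per-spectrum indicator results."""

    id: str
    total_area: float = float("nan")
    i1400: float = float("nan")
    is_baseline_corrected: bool = None
    c_wv: float = float("nan")
    se_c_wv: float = float("nan")
    c_co2: float = float("nan")
    se_c_co2: float = float("nan")
    c_noise: float = float("nan")
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------


def baseline_diagnostic(s: Spectrum, cfg: QCConfig = None):
    """(i1400, is_baseline_corrected) for one spectrum.

    i1400 is the rubberband baseline of the CO2-bridged, area-clipped
    spectrum, clipped to the detector window, divided by the total area and
    read at the evaluation wavenumber.  The flag is True when
    ``i1400 <= t_bc`` (already corrected spectra sit at ~0).
    """
    cfg = cfg or QCConfig()
    res = area_pipeline(s, cfg)
    area = float(np.sum(res.spectrum.intensities))
    if area == 0:
        raise DegenerateSpectrumError(f"total area of {s.id!r} is 0")
    window = clip(res.baseline, *cfg.bc_clip_range)
    i1400 = intensity_at(window, cfg.bc_eval) / area
    return i1400, bool(i1400 <= cfg.t_bc)


def artifact_contribution(
    s: Spectrum,
    ref: ReferenceSpectrum,
    a: float,
    b: float,
    peak_max: float,
    cfg: QCConfig = None,
    area: float = None,
    ref_area: float = None,
):
    """Relative contribution of a gas reference to a spectrum: (c, se).

    Both the query and the reference pass through the identical path —
    signed peak extraction over [a, b] followed by division by the
    respective total area — before the OLS slope of query on reference is
    taken.  The symmetric treatment calibrates the estimator so that
    c(reference) = 1 exactly.

    ``area``/``ref_area`` allow reuse of precomputed total areas.
    """
    cfg = cfg or QCConfig()
    if not s.covers(a, b):
        raise CoverageError(
            f"spectrum {s.id!r} does not cover the artifact range [{a}, {b}]"
        )
    from .preprocess import total_area  # local import avoids cycle at module load

    if area is None:
        area = total_area(s, cfg)
    if ref_area is None:
        ref_area = total_area(ref.spectrum, cfg)
    if area == 0 or ref_area == 0:
        raise DegenerateSpectrumError("zero total area in artifact contribution")
    query = extract_peak(s, a, b, peak_max).intensities / area
    refq = extract_peak(ref.spectrum, a, b, peak_max).intensities / ref_area
    if query.size != refq.size:
        # grids differ: re-interpolate the reference region onto the query grid
        qs = extract_peak(s, a, b, peak_max)
        rs = extract_peak(ref.spectrum, a, b, peak_max)
        refq = np.interp(qs.wavenumbers, rs.wavenumbers, rs.intensities) / ref_area
    return linear_fit(refq, query)


def water_vapor_contribution(s, ref_wv, cfg: QCConfig = None, **kw):
    """c_wv and its standard error (window and peak from the config)."""
    cfg = cfg or QCConfig()
    return artifact_contribution(
        s, ref_wv, *cfg.wv_range, cfg.wv_peak_max, cfg, **kw
    )


def co2_contribution(s, ref_co2, cfg: QCConfig = None, **kw):
    """c_co2 and its standard error (window and peak from the config)."""
    cfg = cfg or QCConfig()
    return artifact_contribution(
        s, ref_co2, *cfg.co2_range, cfg.co2_peak_max, cfg, **kw
    )


def noise_level(s: Spectrum, cfg: QCConfig = None) -> float:
    """Relative noise level c_noise of one spectrum.

    Area pipeline (clip, CO2 bridge, rubberband), Savitzky-Golay residual,
    division by the sum of the corrected intensities, clip to the noise
    window, sample variance.  Invariant under uniform intensity scaling and
    affine baseline addition.
    """
    cfg = cfg or QCConfig()
    corrected = area_pipeline(s, cfg).spectrum
    total = float(np.sum(corrected.intensities))
    if total == 0:
        raise DegenerateSpectrumError(f"zero normalising sum for {s.id!r}")
    resid = savgol_residual(corrected, cfg.savgol_window, cfg.savgol_order)
    rel = resid.with_intensities(resid.intensities / total)
    window = clip(rel, *cfg.noise_range)
    return float(np.var(window.intensities, ddof=1))


# ---------------------------------------------------------------------------
# Batch report
# ---------------------------------------------------------------------------


def qc_record(
    s: Spectrum,
    ref_wv: ReferenceSpectrum = None,
    ref_co2: ReferenceSpectrum = None,
    cfg: QCConfig = None,
    ref_areas: dict = None,
) -> QCRecord:
    """All indicators for one spectrum; per-indicator failures become flags."""
    cfg = cfg or QCConfig()
    rec = QCRecord(id=s.id)
    ref_areas = ref_areas if ref_areas is not None else {}
    # ATR-like spectra may stop short of the full area range: compute A over
    # the available overlap and flag it, instead of losing every indicator
    a0, b0 = cfg.area_range
    aa, bb = max(a0, s.wmin), min(b0, s.wmax)
    if (aa, bb) != (a0, b0):
        lo, hi = cfg.co2_interp_range
        if not (aa < lo and hi < bb):
            rec.flags.append(
                f"area: spectrum range [{s.wmin}, {s.wmax}] cannot host the "
                f"area pipeline"
            )
            return rec
        cfg = dataclasses.replace(cfg, area_range=(aa, bb))
        rec.flags.append(f"area: partial coverage [{aa}, {bb}] of [{a0}, {b0}]")
    try:
        res = area_pipeline(s, cfg)
    except MirqcError as exc:
        rec.flags.append(f"area: {exc}")
        return rec
    rec.total_area = float(np.sum(res.spectrum.intensities))
    try:
        rec.i1400, rec.is_baseline_corrected = baseline_diagnostic(s, cfg)
    except MirqcError as exc:
        rec.flags.append(f"baseline: {exc}")
    for name, ref, fn in (
        ("c_wv", ref_wv, water_vapor_contribution),
        ("c_co2", ref_co2, co2_contribution),
    ):
        if ref is None:
            rec.flags.append(f"{name}: no reference supplied")
            continue
        try:
            if ref.spectrum.id not in ref_areas:
                from .preprocess import total_area

                ref_areas[ref.spectrum.id] = total_area(ref.spectrum, cfg)
            c, se = fn(
                s, ref, cfg, area=rec.total_area, ref_area=ref_areas[ref.spectrum.id]
            )
            setattr(rec, name, c)
            setattr(rec, "se_" + name, se)
        except MirqcError as exc:
            rec.flags.append(f"{name}: {exc}")
    try:
        rec.c_noise = noise_level(s, cfg)
    except MirqcError as exc:
        rec.flags.append(f"noise: {exc}")
    return rec


def qc_report(
    batch,
    ref_wv: ReferenceSpectrum = None,
    ref_co2: ReferenceSpectrum = None,
    cfg: QCConfig = None,
    include_hi: bool = False,
) -> pd.DataFrame:
    """QC report for a batch of spectra, one row per spectrum.

    Columns follow the database metadata-table names; missing indicators are
    emitted as empty cells with an entry in ``flags``.  ``include_hi`` adds
    the 1630/1090 humification index of the raw input spectra.
    """
    cfg = cfg or QCConfig()
    ref_areas: dict = {}
    rows = []
    for s in batch:
        rec = qc_record(s, ref_wv, ref_co2, cfg, ref_areas)
        logger.info(
            "qc %s: A=%.6g i1400=%.3g bc=%s c_wv=%.3g c_co2=%.3g noise=%.3g flags=%d",
            rec.id, rec.total_area, rec.i1400, rec.is_baseline_corrected,
            rec.c_wv, rec.c_co2, rec.c_noise, len(rec.flags),
        )
        row = {
            "id": rec.id,
            "is_baseline_corrected": rec.is_baseline_corrected,
            "mir_water_vapor_contribution_relative": rec.c_wv,
            "mir_water_vapor_contribution_relative_sd": rec.se_c_wv,
            "mir_co2_contribution_relative": rec.c_co2,
            "mir_co2_contribution_relative_sd": rec.se_c_co2,
            "noise_level_relative": rec.c_noise,
            "i1400": rec.i1400,
            "total_area": rec.total_area,
            "flags": "; ".join(rec.flags),
        }
        if include_hi:
            from .indices import humification_index

            try:
                row["hi_1630_1090"] = humification_index(s).value
            except MirqcError as exc:
                row["hi_1630_1090"] = float("nan")
                row["flags"] = "; ".join(rec.flags + [f"hi: {exc}"])
        rows.append(row)
    columns = REPORT_COLUMNS + (["hi_1630_1090"] if include_hi else [])
    return pd.DataFrame(rows, columns=columns)
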