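"""Derivation of pure-gas reference spectra from pairs of background scans.

FTIR background (single-beam) scans taken at different times differ in their
atmospheric water-vapor and CO2 content.  Ratioing two background scans
cancels the instrument response, and the absorbance of the ratio is, up to
drift, the difference of the two gas columns — an approximately *pure* gas
spectrum.  The CO2 reference keeps only the asymmetric-stretch doublet
(everything from 728-2230 cm^-1 and above 3800 cm^-1 is replaced by straight
lines); the water-vapor reference keeps the rotational-vibrational line
combs, is cleaned of residual CO2 by atmospheric correction against the CO2
reference, anchored to zero at 2000 cm^-1 (a region free of gas lines), and
clamped to non-negative values.

Device-to-reference assignment: references cannot be derived for every
spectrometer (raw background scans are often missing), so a YAML lookup maps
each device to the reference ids to use, with a declared default for unknown
devices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import AnchorError, DegenerateReferenceError, FitError
from .preprocess import chord_fill, replace_region_linear, rubberband
from .spectrum import (
    Spectrum,
    clip,
    interpolate_to_grid,
    nearest_index,
    read_spectra,
    to_absorbance,
    write_spectra,
)

logger = logging.getLogger(__name__)

SPECIES = ("water_vapor", "co2")

#: regions replaced by straight lines in the CO2 reference (plus > 3800)
CO2_FLAT_RANGE = (728.0, 2230.0)
CO2_TAIL_START = 3800.0
#: regions replaced by straight lines in the water-vapor reference
WV_FLAT_RANGES = ((600.0, 1200.0), (2200.0, 3300.0))
WV_ANCHOR = 2000.0
#: fit window for the atmospheric CO2 correction
CO2_FIT_RANGE = (2250.0, 2450.0)
#: a pair is degenerate when the ratio absorbance never exceeds this
DEGENERATE_ABS = 1e-6


@dataclass
class BackgroundPair:
    """Two background scans from the same device, in transmission mode."""

    bg_a: Spectrum
    bg_b: Spectrum
    device: str = "unknown"
    recorded_on: str = None

    def __post_init__(self) -> None:
        for s in (self.bg_a, self.bg_b):
            if s.mode != "transmission":
                raise ValueError(
                    f"background {s.id!r} must be transmission mode, got {s.mode!r}"
                )


@dataclass
class ReferenceSpectrum:
    """Derived pure-gas spectrum with provenance."""

    spectrum: Spectrum
    species: str
    device: str = "unknown"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")


def _replace_clamped(s: Spectrum, a: float, b: float) -> Spectrum:
    """Straight line over [a, b] intersected with the spectral range.

    Like :func:`~mirqc.preprocess.replace_region_linear`, but when the region
    runs past the spectrum boundary the boundary point itself serves as the
    chord anchor instead of raising.
    """
    w = s.wavenumbers
    inside = np.flatnonzero((w >= a) & (w <= b))
    if inside.size < 3:
        return s
    lo, hi = int(inside[0]), int(inside[-1])
    y = s.intensities.copy()
    chord_fill(y, w, lo, hi)
    return s.with_intensities(y)


def _ratio_absorbance(pair: BackgroundPair) -> Spectrum:
    """Absorbance of bg_a / bg_b on bg_a's grid, interpolated to dw = 1."""
    a, b = pair.bg_a, pair.bg_b
    if not np.array_equal(a.wavenumbers, b.wavenumbers):
        yb = np.interp(a.wavenumbers, b.wavenumbers, b.intensities)
        b = a.with_intensities(yb, id=b.id, mode="transmission")
    ratio = a.with_intensities(
        a.intensities / np.maximum(b.intensities, 1e-30),
        id=f"{a.id}/{b.id}",
        mode="ratio",
    )
    return interpolate_to_grid(to_absorbance(ratio), dw=1.0)


def derive_co2_reference(pair: BackgroundPair) -> ReferenceSpectrum:
    """Derive an approximately pure CO2 absorbance spectrum from a pair.

    ratio -> absorbance -> integer grid -> straight lines over 728-2230 and
    above 3800 cm^-1 -> rubberband correction.
    """
    absr = _ratio_absorbance(pair)
    if float(np.nanmax(np.abs(absr.intensities))) < DEGENERATE_ABS:
        raise DegenerateReferenceError(
            f"backgrounds {pair.bg_a.id!r} and {pair.bg_b.id!r} are nearly "
            "identical; no gas signal to derive a reference from"
        )
    flat = replace_region_linear(absr, *CO2_FLAT_RANGE)
    # above 3800: anchors are the grid point at/just above 3800 and the last point
    w, y = flat.wavenumbers, flat.intensities.copy()
    lo = int(np.searchsorted(w, CO2_TAIL_START))
    if lo < w.size - 2:
        chord_fill(y, w, lo, w.size - 1)
    flat = flat.with_intensities(y)
    corrected = rubberband(flat).spectrum
    return ReferenceSpectrum(
        spectrum=corrected.with_intensities(corrected.intensities, id=f"co2:{pair.device}"),
        species="co2",
        device=pair.device,
        provenance=[
            f"ratio {pair.bg_a.id}/{pair.bg_b.id}",
            "to_absorbance",
            "interpolate dw=1",
            f"replace_region_linear {CO2_FLAT_RANGE}",
            f"replace_region_linear >={CO2_TAIL_START}",
            "rubberband",
        ],
    )


def atmospheric_correct(s: Spectrum, ref: ReferenceSpectrum, fit_range=CO2_FIT_RANGE) -> Spectrum:
    """Subtract the reference scaled by the OLS slope fitted in ``fit_range``.

    The slope comes from regressing the spectrum on the reference (with
    intercept) within the fit window; the scaled reference is subtracted over
    the full shared grid.
    """
    rs = ref.spectrum
    if not np.array_equal(s.wavenumbers, rs.wavenumbers):
        rs = s.with_intensities(
            np.interp(s.wavenumbers, rs.wavenumbers, rs.intensities), id=rs.id
        )
    sq = clip(s, *fit_range)
    rq = clip(rs, *fit_range)
    x, y = rq.intensities, sq.intensities
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise FitError("reference has zero variance in the fit range")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    return s.with_intensities(s.intensities - slope * rs.intensities)


def derive_water_vapor_reference(
    pair: BackgroundPair, co2_ref: ReferenceSpectrum
) -> ReferenceSpectrum:
    """Derive an approximately pure water-vapor absorbance spectrum.

    ratio -> absorbance -> integer grid -> atmospheric correction with the
    CO2 reference -> scale so the intensity at 2000 cm^-1 equals 1 ->
    subtract 1 -> clamp negatives to 0 -> straight lines over 600-1200 and
    2200-3300 cm^-1.  The result is non-negative and exactly 0 at the anchor.
    """
    if co2_ref.species != "co2":
        raise ValueError("co2_ref must have species 'co2'")
    absr = _ratio_absorbance(pair)
    if float(np.nanmax(np.abs(absr.intensities))) < DEGENERATE_ABS:
        raise DegenerateReferenceError(
            f"backgrounds {pair.bg_a.id!r} and {pair.bg_b.id!r} are nearly "
            "identical; no gas signal to derive a reference from"
        )
    corr = atmospheric_correct(absr, co2_ref)
    anchor_val = corr.intensities[nearest_index(corr, WV_ANCHOR)]
    if anchor_val <= 0:
        raise AnchorError(
            f"intensity at {WV_ANCHOR} cm^-1 is {anchor_val}; cannot anchor"
        )
    y = corr.intensities / anchor_val - 1.0
    y = np.maximum(y, 0.0)
    out = corr.with_intensities(y, id=f"water_vapor:{pair.device}")
    for rng in WV_FLAT_RANGES:
        out = _replace_clamped(out, *rng)
    return ReferenceSpectrum(
        spectrum=out,
        species="water_vapor",
        device=pair.device,
        provenance=[
            f"ratio {pair.bg_a.id}/{pair.bg_b.id}",
            "to_absorbance",
            "interpolate dw=1",
            f"atmospheric_correct co2 over {CO2_FIT_RANGE}",
            f"anchor at {WV_ANCHOR} (divide, subtract 1, clamp >= 0)",
            f"replace_region_linear {WV_FLAT_RANGES[0]}",
            f"replace_region_linear {WV_FLAT_RANGES[1]}",
        ],
    )


# ---------------------------------------------------------------------------
# Persistence and device lookup
# ---------------------------------------------------------------------------


def write_reference(ref: ReferenceSpectrum, csv_path, yaml_path=None) -> None:
    """Persist a reference as wide CSV plus a YAML provenance sidecar."""
    write_spectra([ref.spectrum], csv_path, dialect="wide")
    yaml_path = yaml_path or Path(csv_path).with_suffix(".yml")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(
            {
                "species": ref.species,
                "device": ref.device,
                "provenance": ref.provenance,
            },
            fh,
            sort_keys=False,
        )


def read_reference(csv_path, yaml_path=None) -> ReferenceSpectrum:
    batch = read_spectra(csv_path, dialect="wide", mode="absorbance")
    if len(batch) != 1:
        raise ValueError(f"reference CSV {csv_path} must contain exactly one spectrum")
    yaml_path = yaml_path or Path(csv_path).with_suffix(".yml")
    meta = {}
    if Path(yaml_path).exists():
        with open(yaml_path) as fh:
            meta = yaml.safe_load(fh) or {}
    species = meta.get("species")
    if species is None:
        # fall back to the spectrum id convention "species:device"
        species = batch[0].id.split(":")[0]
    return ReferenceSpectrum(
        spectrum=batch[0],
        species=species,
        device=meta.get("device", "unknown"),
        provenance=meta.get("provenance", []),
    )


class DeviceLookup:
    """Maps a measurement device to the reference ids to use for it.

    YAML layout::

        default: {water_vapor: wv_vector22, co2: co2_vector22}
        devices:
          "Bruker Vector 22": {water_vapor: wv_vector22, co2: co2_vector22}

    Unknown devices fall back to ``default`` with a logged warning, mirroring
    the cross-device reuse of references when per-device backgrounds are
    unavailable.
    """

    def __init__(self, default: dict, devices: dict = None):
        self.default = dict(default)
        self.devices = {k: dict(v) for k, v in (devices or {}).items()}

    @classmethod
    def from_yaml(cls, path) -> "DeviceLookup":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "default" not in data:
            raise ValueError(f"device lookup {path} needs a 'default' entry")
        return cls(data["default"], data.get("devices"))

    def resolve(self, device: str) -> dict:
        if device in self.devices:
            return self.devices[device]
        logger.warning(
            "no reference assignment for device %r; using default %r",
            device,
            self.default,
        )
        return self.default
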