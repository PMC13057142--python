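"""Synthetic mid-infrared spectra with known ground truth.

Emulates organic-matter absorbance spectra as sums of broad Gaussian bands
(O-H/N-H ~3400, aliphatic C-H 2920/2850, C=O 1720, aromatic/carboxylate
1630, 1510, 1420, polysaccharide C-O 1090 cm^-1), plus an additive baseline
(offset + slope + exponential decay, as produced by scattering), atmospheric
artifact combs (a water-vapor line comb and the CO2 asymmetric-stretch
doublet), and iid Gaussian intensity noise.  Every stochastic element flows
through one seeded generator per call; the truth parameters travel with the
spectrum so every QC indicator can be checked against a known answer.

The artifact combs are stylised (a handful of Gaussian lines at fixed
positions), not HITRAN line lists: they reproduce the *locations* the QC
windows key on (a water-vapor local maximum at 3853 cm^-1, CO2 doublet at
2340/2362 cm^-1 plus the 668 cm^-1 bending line), which is what the
indicators are sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCConfig
from .preprocess import extract_peak, total_area
from .reference import BackgroundPair, ReferenceSpectrum
from .spectrum import SpectraBatch, Spectrum

#: organic-matter bands: (center cm^-1, Gaussian sigma cm^-1, relative height)
DEFAULT_PEAKS = (
    (3400.0, 150.0, 0.55),
    (2920.0, 28.0, 0.22),
    (2850.0, 22.0, 0.12),
    (1720.0, 25.0, 0.28),
    (1630.0, 40.0, 0.45),
    (1510.0, 22.0, 0.18),
    (1420.0, 30.0, 0.30),
    (1090.0, 55.0, 0.75),
)

#: global intensity scale; chosen so the default spectrum has total area
#: A ~ 100 on the [699, 3999] grid (calibrated once, frozen)
HEIGHT_SCALE = 0.234


def gaussian(w: np.ndarray, center: float, sigma: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((w - center) / sigma) ** 2)


@dataclass
class ArtifactTruth:
    """Ground-truth parameters of one synthetic spectrum."""

    peaks: tuple = DEFAULT_PEAKS
    #: additive baseline: offset + slope*(w - wmin) + amp*exp(-(w - wmin)/rate)
    baseline: tuple = (0.0, 0.0, 0.0, 800.0)
    wv_scale: float = 0.0
    co2_scale: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c, sig, h in self.peaks:
            if sig <= 0:
                raise ValueError(f"peak width must be > 0 (center {c})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_grid(wmin: float = 650.0, wmax: float = 3999.0, dw: float = 1.0) -> np.ndarray:
    return np.arange(wmin, wmax + dw / 2, dw)


# ---------------------------------------------------------------------------
# Artifact combs
# ---------------------------------------------------------------------------


def _wv_line_list():
    lines = []
    for k, c in enumerate(np.arange(1302.0, 1900.0, 25.0)):
        lines.append((c, 2.0, 0.8 if k % 2 == 0 else 0.5))
    for k in range(-23, 5):
        c = 3853.0 + 15.0 * k
        h = 1.0 if k == 0 else (0.7 if k % 2 == 0 else 0.45)
        lines.append((c, 2.0, h))
    return lines


_CO2_LINES = ((2362.0, 6.0, 1.0), (2340.0, 6.0, 0.8), (668.0, 4.0, 0.4))


def make_artifact_comb(species: str, grid: np.ndarray = None) -> Spectrum:
    """Stylised pure-gas line comb on the given grid, unit maximum.

    ``water_vapor``: narrow alternating Gaussian lines over 1300-1900 and
    3500-3920 cm^-1 with the local maximum at 3853 cm^-1.  ``co2``: the
    2340/2362 cm^-1 doublet plus the 668 cm^-1 bending line.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if species == "water_vapor":
        lines = _wv_line_list()
    elif species == "co2":
        lines = _CO2_LINES
    else:
        raise ValueError(f"unknown species {species!r}")
    y = np.zeros_like(grid)
    for c, sig, h in lines:
        y += gaussian(grid, c, sig, h)
    return Spectrum(
        f"comb:{species}", grid, y / y.max(), mode="absorbance",
        metadata={"species": species},
    )


# ---------------------------------------------------------------------------
# Sample spectra
# ---------------------------------------------------------------------------


def simulate_spectrum(
    truth: ArtifactTruth = None, grid: np.ndarray = None, id: str = None
):
    """Generate one synthetic spectrum; returns (spectrum, truth)."""
    truth = truth or ArtifactTruth()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 10:
        raise ValueError("grid too short for a meaningful spectrum")
    y = np.zeros_like(grid)
    for c, sig, h in truth.peaks:
        y += gaussian(grid, c, sig, h * HEIGHT_SCALE)
    off, slope, amp, rate = truth.baseline
    y += off + slope * (grid - grid[0]) + amp * np.exp(-(grid - grid[0]) / rate)
    if truth.wv_scale:
        y += truth.wv_scale * make_artifact_comb("water_vapor", grid).intensities
    if truth.co2_scale:
        y += truth.co2_scale * make_artifact_comb("co2", grid).intensities
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, grid.size)
    s = Spectrum(
        id or f"sim:{truth.seed}", grid, y, mode="absorbance",
        metadata={"seed": str(truth.seed), "wv_scale": str(truth.wv_scale),
                  "co2_scale": str(truth.co2_scale), "noise_sd": str(truth.noise_sd)},
    )
    return s, truth


# ---------------------------------------------------------------------------
# Background pairs
# ---------------------------------------------------------------------------


def simulate_background_pair(
    seed: int,
    wv_delta: float = 0.02,
    co2_delta: float = 0.2,
    grid: np.ndarray = None,
    noise_sd: float = 1e-5,
) -> BackgroundPair:
    """Two transmission-mode background scans differing in gas content.

    ``bg_b`` is a smooth source-emission envelope with a shared atmospheric
    column; ``bg_a`` additionally absorbs ``co2_delta`` of the CO2 comb and
    ``wv_delta`` of the water-vapor comb, plus a small smooth between-scan
    drift whose amplitude scales with the concentration differences (two
    scans with equal gas content were taken back-to-back and carry no
    drift, so the ratio is exactly 1).
    """
    if wv_delta < 0 or co2_delta < 0:
        raise ValueError("deltas must be >= 0")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    span = grid[-1] - grid[0]
    env_amp = 0.35 * (1.0 + 0.05 * rng.standard_normal())
    env_center = 2300.0 + 50.0 * rng.standard_normal()
    envelope = 0.55 + env_amp * np.exp(-(((grid - env_center) / 1300.0) ** 2))
    wv = make_artifact_comb("water_vapor", grid).intensities
    co2 = make_artifact_comb("co2", grid).intensities
    shared = 0.08 * wv + 0.05 * co2
    drift_amp = 0.02 * (wv_delta + co2_delta)
    drift = drift_amp * (0.7 + 0.3 * (grid - grid[0]) / span)
    t_b = envelope * 10.0 ** (-shared)
    t_a = t_b * 10.0 ** (-(co2_delta * co2 + wv_delta * wv + drift))
    if noise_sd > 0:
        t_a = t_a + rng.normal(0.0, noise_sd, grid.size)
        t_b = t_b + rng.normal(0.0, noise_sd, grid.size)
    bg_a = Spectrum(f"bg_a:{seed}", grid, t_a, mode="transmission")
    bg_b = Spectrum(f"bg_b:{seed}", grid, t_b, mode="transmission")
    return BackgroundPair(bg_a=bg_a, bg_b=bg_b, device=f"synthetic-device-{seed}")


# ---------------------------------------------------------------------------
# Artifact injection with exact relative contribution
# ---------------------------------------------------------------------------


def inject_artifacts(s: Spectrum, specs, cfg: QCConfig = None) -> Spectrum:
    """Add reference-shaped artifacts so each has relative contribution alpha.

    ``specs`` is a sequence of ``(ref, alpha, (a, b), peak_max)``.  The
    injected shape is the processed (peak-extracted, area-normalised)
    reference region — exactly the regressor the contribution estimator
    uses.  Because the injection itself enlarges the spectrum's total area
    A, the injection amplitudes are solved self-consistently so the *final*
    spectrum has contribution alpha relative to its own area:

        A_final = A_clean / (1 - sum_i alpha_i * f_i),   beta_i = alpha_i * A_final

    with f_i the in-region sum of the normalised reference shape.
    """
    cfg = cfg or QCConfig()
    a_clean = total_area(s, cfg)
    bridge_lo, bridge_hi = cfg.co2_interp_range
    shapes = []
    denom = 1.0
    for ref, alpha, (a, b), peak_max in specs:
        region = extract_peak(ref.spectrum, a, b, peak_max)
        x = region.intensities / total_area(ref.spectrum, cfg)
        # mass injected strictly inside the CO2 bridge interval never reaches
        # A (the area pipeline replaces it with a chord), so it is excluded
        # from the area-budget term f
        outside_bridge = ~(
            (region.wavenumbers > bridge_lo) & (region.wavenumbers < bridge_hi)
        )
        f = float(np.sum(x[outside_bridge]))
        denom -= alpha * f
        shapes.append((region.wavenumbers, x, alpha))
    if denom <= 0:
        raise ValueError("requested contributions exceed the spectrum's area budget")
    a_final = a_clean / denom
    y = s.intensities.copy()
    for wreg, x, alpha in shapes:
        idx = np.searchsorted(s.wavenumbers, wreg)
        if not np.allclose(s.wavenumbers[idx], wreg):
            raise ValueError("spectrum grid does not contain the reference region grid")
        y[idx] += alpha * a_final * x
    return s.with_intensities(y)


def simulate_validation_batch(
    n: int,
    ref_wv: ReferenceSpectrum,
    ref_co2: ReferenceSpectrum,
    seed: int = 0,
    cfg: QCConfig = None,
    noise_sd: float = 2e-4,
):
    """A batch of synthetic sample spectra with known artifact contributions.

    Per spectrum: band heights jittered (+-15%), water-vapor contribution
    drawn uniformly from [0, 1], CO2 contribution from [-0.5, 1].  Noise is
    added *before* injection so the truth contribution is defined relative
    to the spectrum's actual total area — the rubberband area of a noisy
    spectrum sits slightly above the noiseless one (the hull hugs noise
    minima), and a contribution "relative to the spectrum" means relative
    to the spectrum as measured.  Returns (batch, truth table).
    """
    cfg = cfg or QCConfig()
    rng = np.random.default_rng(seed)
    spectra, rows = [], []
    for i in range(n):
        jitter = 1.0 + 0.15 * rng.uniform(-1, 1, len(DEFAULT_PEAKS))
        peaks = tuple(
            (c, sig, h * j) for (c, sig, h), j in zip(DEFAULT_PEAKS, jitter)
        )
        truth = ArtifactTruth(peaks=peaks, noise_sd=0.0, seed=seed + i)
        clean, _ = simulate_spectrum(truth, id=f"val:{i:04d}")
        if noise_sd > 0:
            clean = clean.with_intensities(
                clean.intensities + rng.normal(0.0, noise_sd, len(clean))
            )
        alpha_wv = float(rng.uniform(0.0, 1.0))
        alpha_co2 = float(rng.uniform(-0.5, 1.0))
        s = inject_artifacts(
            clean,
            [
                (ref_wv, alpha_wv, cfg.wv_range, cfg.wv_peak_max),
                (ref_co2, alpha_co2, cfg.co2_range, cfg.co2_peak_max),
            ],
            cfg,
        )
        spectra.append(s)
        rows.append(
            {"id": s.id, "alpha_wv": alpha_wv, "alpha_co2": alpha_co2,
             "noise_sd": noise_sd}
        )
    return SpectraBatch(spectra), pd.DataFrame(rows)
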