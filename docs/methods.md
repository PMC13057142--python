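# Methods

This note records the model behind each quality indicator, the defaults and
why they are what they are, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the procedure was
genuinely open.

## Spectra and preprocessing

A spectrum is a strictly increasing wavenumber grid (cm⁻¹) with intensities
in absorbance (AU), transmission (fraction), or dimensionless ratio mode.
All QC statistics operate on the integer 1 cm⁻¹ grid produced by linear
interpolation (`interpolate_to_grid`, no extrapolation; interior missing
values are bridged linearly, leading/trailing missing values dropped —
the QC windows must be contiguous).  Transmission-to-absorbance conversion
is A = −log₁₀ T with T clamped at 10⁻⁸ to avoid infinities in
ratio-derived spectra.  Wavenumber intervals are closed; point lookups use
the nearest grid point with ties broken toward the lower wavenumber.

**Rubberband baseline.**  The baseline is the lower convex hull of the
(ν, I) point set (Andrew's monotone chain, collinear interior points
dropped), interpolated piecewise-linearly between hull vertices and
subtracted.  This is deterministic, idempotent, removes affine baselines
exactly, and leaves corrected intensities ≥ 0 with zeros at hull vertices.
A consequence worth remembering: the hull of a *convex* baseline (e.g. an
exponential scattering decay) is the baseline itself, so rubberband removes
convex drift essentially completely, while concave bumps are only chorded.

**Total area A.**  Clip to [699, 3999] cm⁻¹ → replace [2250, 2450] cm⁻¹ by
the chord between its boundary grid points (negative CO₂ doublets would
otherwise punch through the hull and corrupt the baseline) → rubberband →
sum of intensities.  A normalises every relative indicator.

## Indicators

**Baseline detector.**  i1400 = (rubberband *baseline* of the bridged,
clipped spectrum, clipped to [1400, 3400] cm⁻¹, divided by A, evaluated at
1400 cm⁻¹).  Flag `is_baseline_corrected = (i1400 ≤ t_bc)`, t_bc = 9·10⁻⁵.
The flag orientation follows the physical logic (corrected spectra have
near-zero normalised baseline); both i1400 and the flag are reported so the
opposite convention can be re-derived.  On synthetic spectra the separation
is ~3 orders of magnitude (i1400 ≈ 4·10⁻⁷ for corrected spectra with
noise sd 10⁻⁴, ≈ 8·10⁻⁴ after adding a 0.2 AU exponential baseline).

**Signed window extraction.**  `extract_peak(s, [a,b], peak_max)` clips to
the window and compares the intensity at the grid point nearest `peak_max`
with the chord joining the window's endpoint intensities; at or above the
chord the window is rubberband-corrected directly (output ≥ 0), below it
the window is negated, corrected, and negated back (output ≤ 0).  Ties
count as positive; the threshold is exactly 0.

**Artifact contributions.**  Query and reference windows pass through the
*identical* path — extraction followed by division by the respective total
area — and c is the OLS slope (with intercept) of query on reference, SE
from the classical iid-error formula.  The symmetric treatment guarantees
the calibration identity c(reference) = 1 bitwise: the regression is solved
with the closed-form centred formulas, so identical inputs give slope
Sxy/Sxx = 1.0 exactly, zero intercept, zero residuals, SE = 0.  Windows:
water vapor [3780, 3920] cm⁻¹ / peak 3853; CO₂ [2250, 2450] cm⁻¹ / peak
2362.  When a spectrum does not cover a window the indicator is reported
missing with a flag rather than failing the whole record; a spectrum that
stops short of the full [699, 3999] cm⁻¹ area range (ATR-like) gets A
computed over the available overlap, flagged `partial coverage`.

**Noise.**  c_noise = sample variance over [2700, 2750] cm⁻¹ (51 points) of
(area-pipeline output − its Savitzky–Golay smooth) / (sum of the
area-pipeline output).  Savitzky–Golay defaults: window 21 points, order 3
— wide enough that broad organic bands stay in the smooth component, narrow
enough that per-point noise stays in the residual (the residual of iid
noise retains ≈ 80% of its variance at these settings).  Dividing the
residual (rather than the smooth) by the spectral sum makes c_noise
invariant under uniform intensity scaling and affine baselines.

## Reference-spectrum derivation

CO₂: ratio of the two background scans → absorbance → integer grid →
straight lines over 728–2230 cm⁻¹ and above 3800 cm⁻¹ (anchored at the
3800-adjacent point and the final point) → rubberband.  A pair whose ratio
absorbance never exceeds 10⁻⁶ is rejected as degenerate.

Water vapor: ratio → absorbance → integer grid → atmospheric correction
against the CO₂ reference (OLS slope fitted over [2250, 2450] cm⁻¹,
scaled reference subtracted over the full grid) → divide by the intensity
at 2000 cm⁻¹ (a gas-line-free anchor) so it equals 1 → subtract 1 → clamp
negatives to 0 → straight lines over 600–1200 and 2200–3300 cm⁻¹ (clamped
to the available range when the grid starts above 600 cm⁻¹).  The anchor
is read *before* any baseline removal: after rubberband correction the
anchor intensity would be ≈ 0 and the division ill-posed, so no rubberband
step is applied in this branch.  The result is non-negative with intensity
exactly 0 at the anchor.

Device assignment is a YAML lookup (device → {water_vapor, co2} reference
ids) with a declared default and a logged warning for unknown devices,
mirroring the practice of reusing references across instruments when raw
backgrounds are unavailable.

## Synthetic generator

`simulate_spectrum` builds an organic-matter absorbance spectrum on the
650–3999 cm⁻¹ integer grid as a sum of Gaussian bands (defaults near 3400,
2920, 2850, 1720, 1630, 1510, 1420, 1090 cm⁻¹, heights scaled so the
default spectrum has A ≈ 100, keeping i1400 magnitudes on the scale of real
library spectra), an additive baseline (offset + slope + exponential
decay), optional water-vapor/CO₂ line combs, and iid Gaussian noise; all
randomness flows through one generator seeded per call.  The combs are
stylised: a handful of fixed narrow Gaussian lines reproducing the
positions the QC windows key on (local water-vapor maximum at 3853 cm⁻¹,
CO₂ doublet at 2340/2362 plus the 668 cm⁻¹ bend), not HITRAN line lists,
and no instrument line-shape convolution.  Passing tests therefore show the
indicator *algebra* is right; they do not certify performance on real
rotational-vibrational fine structure.

`simulate_background_pair` produces two transmission scans sharing a smooth
source envelope and a common atmospheric column, with the first scan
absorbing extra `co2_delta`·comb and `wv_delta`·comb, plus a small smooth
between-scan drift (absorbance offset + slope, amplitude
0.02·(wv_delta + co2_delta), i.e. ~5·10⁻³ AU at the defaults).  Real
consecutive background scans always carry such drift, and it is what makes
the 2000 cm⁻¹ anchor of the water-vapor derivation well defined; two
back-to-back scans with equal gas content carry none, so their ratio is
exactly 1 and reference derivation correctly reports a degenerate pair.

**Injection with known truth.**  `inject_artifacts` adds the processed
(extracted, area-normalised) reference shape inside its window.  The
injection enlarges the spectrum's own area, so amplitudes are solved
self-consistently — β = α·A_final with A_final = A_clean/(1 − Σ αᵢfᵢ),
where fᵢ is the in-window sum of the normalised reference shape *excluding*
mass inside the CO₂ bridge interval (which never reaches A).  The truth α
is thus the contribution relative to the spectrum as it will be measured,
which is also why the validation batch adds noise *before* injection: the
hull of a noisy spectrum hugs noise minima and sits ~2.5σ per point above
the noiseless hull, inflating A by ~1.6% at σ = 2·10⁻⁴; defining α against
the noiseless area would build that bias into every comparison.
Validation-batch defaults: 15% band-height jitter, α_wv ~ U(0, 1),
α_CO₂ ~ U(−0.5, 1), noise sd 2·10⁻⁴ AU (a typical good transmission-FTIR
noise floor against ~0.2 AU peak absorbances).

## Known limitations

* **Negative water-vapor artifacts attenuate.**  Downward combs in
  [3780, 3920] cm⁻¹ dip below the global hull; the hull pivots on the dip
  minima across thousands of grid points and inflates A far more than the
  artifact's own area (α = −0.3 inflates A ≈ 3.9×, so c_wv ≈ −0.07).  This
  is inherent to hull-based area normalisation — it is exactly why the CO₂
  window is bridged before the hull, and no such protection exists for the
  water-vapor window.  The sign and the window-level amplitude are still
  recovered (~1%); only the area normalisation degrades.  Negative CO₂
  artifacts are unaffected (the bridge protects A) and recover exactly.
* **The classical slope SE is optimistic under the null.**  For artifact-free
  noisy spectra the hull-corrected window residuals are correlated, and the
  measured null sd of c is ~2.2× the reported SE.  With a real injected
  artifact the SE is well calibrated (3·SE covers the truth for ~100% of
  validation-batch spectra).  Treat SEs of near-zero contributions as lower
  bounds.
* Binary instrument formats (SPC/JCAMP) are not parsed; convert to CSV
  externally.  ATR-specific corrections (penetration depth), scatter
  corrections and derivative spectra are out of scope.
* The baseline detector's t_bc was chosen for area-normalised spectra with
  A on the order of 10²; grossly different intensity conventions should
  re-examine it (it is a config field, not a constant).

## Problem sizes used by the test suite

The acceptance-style tests run the detector suite on 100 spectra, the noise
grid on 3 × 50 seeds, and the batch report on 500 spectra — sizes at which
every Monte-Carlo check is stable across seeds while the whole suite stays
interactive (~half a minute).
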