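# mirqc

Quality control for mid-infrared (MIR) absorbance spectra of organic matter
— peat, peat-forming vegetation, dissolved organic matter — of the kind
collected in legacy FTIR spectral libraries.  Spectra contributed to such
collections arrive in mixed states: some already baseline corrected, some
raw; some contaminated by atmospheric water-vapor or CO₂ lines (when the gas
content during the sample scan differed from the background scan); some
noisy.  `mirqc` computes, per spectrum, the four indicators needed to filter
such a collection, plus the tooling around them:

* a **baseline-correction detector**,
* the **relative water-vapor contribution** c_wv ± SE,
* the **relative CO₂ contribution** c_CO₂ ± SE,
* a **relative noise level** c_noise,

together with derivation of the required pure-gas **reference spectra** from
pairs of background scans, a standard **preprocessing** chain (interpolation,
clipping, rubberband baseline correction, area normalisation), the
**humification index**, and a **synthetic-spectrum generator** with known
ground truth so every indicator is testable without any measured data.

## The statistics

All indicators are normalised by the total baseline-corrected area

```
A(s) = Σ_ν  [ rubberband( bridge_CO₂( s|[699,3999] ) ) ](ν)
```

where `s|[a,b]` clips to the wavenumber interval (cm⁻¹), `bridge_CO₂`
replaces [2250, 2450] cm⁻¹ by a chord (negative CO₂ peaks would corrupt the
hull), and `rubberband` subtracts the lower convex hull of the spectrum.

**Baseline detector.**  `i1400 = B(1400) / A(s)`, where `B` is the rubberband
*baseline* of the bridged spectrum, clipped to [1400, 3400] cm⁻¹.  Organic
matter MIR baselines decay from low wavenumbers towards ~2300 cm⁻¹, so
uncorrected spectra have large `i1400`.  A spectrum is flagged as already
baseline corrected when `i1400 ≤ t_bc` with `t_bc = 9·10⁻⁵`.

**Artifact contributions.**  For gas species g with reference spectrum x_g
and diagnostic window W_g ([3780, 3920] cm⁻¹ with peak point 3853 for water
vapor; [2250, 2450] cm⁻¹ with peak point 2362 for CO₂):

```
q  = extract_peak(s,   W_g) / A(s)          # signed, hull-corrected window
x  = extract_peak(x_g, W_g) / A(x_g)
c_g = OLS slope of q on x (with intercept),  SE from the classical estimator
```

`extract_peak` decides the artifact sign at the diagnostic peak point and
hull-corrects the window on the flipped region for downward (negative)
artifacts, so `c_g` is sign-preserving.  Passing the reference itself as the
query gives `c_g = 1` exactly — the estimator's calibration identity.

**Noise.**  `c_noise` is the sample variance over [2700, 2750] cm⁻¹ (a
peak-free window) of the Savitzky–Golay residual (window 21 points, order 3)
of the area-pipeline output, divided by its sum — invariant under intensity
scaling and affine baselines.

**Reference derivation.**  Ratioing two background scans from the same
instrument cancels the source/detector response and leaves the *difference*
of the two atmospheric gas columns; converting to absorbance, flattening the
non-CO₂ regions (CO₂ reference) or anchoring at the line-free point
2000 cm⁻¹ and clamping (water-vapor reference, after atmospheric correction
against the CO₂ reference) yields approximately pure gas spectra.

## Worked example

```python
import mirqc as m

cfg = m.QCConfig()                       # all windows and thresholds

# derive references from (here: simulated) background-scan pairs
ref_co2 = m.derive_co2_reference(
    m.simulate_background_pair(seed=1, wv_delta=0.02, co2_delta=0.2))
ref_wv = m.derive_water_vapor_reference(
    m.simulate_background_pair(seed=2, wv_delta=0.25, co2_delta=0.05), ref_co2)

# three synthetic sample spectra with known artifact contributions
batch, truth = m.simulate_validation_batch(3, ref_wv, ref_co2, seed=0)
report = m.qc_report(batch, ref_wv, ref_co2, cfg, include_hi=True)
print(report)
```

prints (columns abridged):

```
      id  is_baseline_corrected   c_wv     se_wv    c_co2    se_co2   total_area  hi_1630_1090
val:0000                   True  0.244344  0.000107  -0.125743  3e-06  110.34     0.6146
val:0001                   True  0.185180  0.000101   0.068120  3e-06  114.05     0.6143
val:0002                   True  0.881909  0.000091   0.590075  3e-06  117.43     0.5676
```

The injected ground-truth contributions were `alpha_wv = 0.2443, 0.1852,
0.8819` and `alpha_co2 = −0.1257, 0.0681, 0.5901`: each estimate matches its
truth to a few parts in 10⁴ (within ~1 standard error), negative CO₂
artifacts keep their sign, and all three spectra — generated without an
additive baseline — are flagged as baseline corrected.  In the full report
the contribution columns carry the spectral-library metadata names
(`mir_water_vapor_contribution_relative`, …_sd, `mir_co2_contribution_relative`,
…_sd, `noise_level_relative`).

The same pipelines are available from the shell:

```sh
mirqc simulate -n 10 --seed 3 --out spectra.csv
mirqc derive-ref bg_a.csv bg_b.csv --species co2 --out co2_ref.csv
mirqc qc spectra.csv --ref-wv wv_ref.csv --ref-co2 co2_ref.csv --out report.csv
mirqc preprocess spectra.csv --out preprocessed.csv
```

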