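"""Quality indicators: baseline detector, artifact contributions, noise."""

import numpy as np
import pytest

from mirqc import (
    QCConfig,
    Spectrum,
    baseline_diagnostic,
    clip,
    co2_contribution,
    inject_artifacts,
    noise_level,
    qc_report,
    rubberband,
    simulate_spectrum,
    water_vapor_contribution,
)
from mirqc.errors import CoverageError
from mirqc.qc import REPORT_COLUMNS, linear_fit
from mirqc.synthetic import ArtifactTruth


class TestLinearFit:
    def test_identity_is_float_exact(self, rng):
        x = rng.normal(size=100)
        slope, se = linear_fit(x, x)
        assert slope == 1.0
        assert se == 0.0

    def test_known_line_recovered(self, rng):
        x = rng.normal(size=200)
        y = 3.0 + 2.0 * x
        slope, se = linear_fit(x, y)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_se_matches_textbook_estimator(self, rng):
        x = rng.normal(size=50)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.2, 50)
        slope, se = linear_fit(x, y)
        # independent check via the normal-equations formula
        X = np.column_stack([np.ones_like(x), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (50 - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert slope == pytest.approx(beta[1], abs=1e-12)
        assert se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)


class TestBaselineDiagnostic:
    def test_corrected_spectrum_flagged_corrected(self, clean_spectrum, cfg):
        corrected = rubberband(clean_spectrum).spectrum
        i1400, flag = baseline_diagnostic(corrected, cfg)
        assert abs(i1400) <= cfg.t_bc
        assert flag is True

    def test_curved_baseline_flagged_uncorrected(self, clean_spectrum, cfg):
        corrected = rubberband(clean_spectrum).spectrum
        w = corrected.wavenumbers
        curved = corrected.with_intensities(
            corrected.intensities + 0.2 * np.exp(-(w - w[0]) / 900.0)
        )
        i1400, flag = baseline_diagnostic(curved, cfg)
        assert i1400 > 2 * cfg.t_bc
        assert flag is False

    def test_decision_uses_configured_threshold(self, clean_spectrum):
        corrected = rubberband(clean_spectrum).spectrum
        w = corrected.wavenumbers
        curved = corrected.with_intensities(
            corrected.intensities + 0.2 * np.exp(-(w - w[0]) / 900.0)
        )
        i1400, _ = baseline_diagnostic(curved)
        # with a threshold above the measured i1400 the same spectrum flips
        lax = QCConfig(t_bc=2 * i1400)
        assert baseline_diagnostic(curved, lax)[1] is True
        strict = QCConfig(t_bc=i1400 / 2)
        assert baseline_diagnostic(curved, strict)[1] is False


class TestArtifactContribution:
    def test_self_reference_is_exactly_one(self, ref_wv, ref_co2, cfg):
        c, se = water_vapor_contribution(ref_wv.spectrum, ref_wv, cfg)
        assert c == 1.0 and se == 0.0
        c, se = co2_contribution(ref_co2.spectrum, ref_co2, cfg)
        assert c == 1.0 and se == 0.0

    def test_clean_spectrum_contribution_near_zero(
        self, clean_spectrum, ref_wv, ref_co2, cfg
    ):
        c, _ = water_vapor_contribution(clean_spectrum, ref_wv, cfg)
        assert abs(c) < 1e-3
        c, _ = co2_contribution(clean_spectrum, ref_co2, cfg)
        assert abs(c) < 1e-3

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0])
    def test_positive_recovery_both_species(
        self, clean_spectrum, ref_wv, ref_co2, cfg, alpha
    ):
        s = inject_artifacts(
            clean_spectrum, [(ref_wv, alpha, cfg.wv_range, cfg.wv_peak_max)], cfg
        )
        c, _ = water_vapor_contribution(s, ref_wv, cfg)
        assert abs(c - alpha) <= 0.05 * max(alpha, 0.1)
        s = inject_artifacts(
            clean_spectrum, [(ref_co2, alpha, cfg.co2_range, cfg.co2_peak_max)], cfg
        )
        c, _ = co2_contribution(s, ref_co2, cfg)
        assert abs(c - alpha) <= 0.05 * max(alpha, 0.1)

    def test_negative_co2_recovery(self, clean_spectrum, ref_co2, cfg):
        """The CO2 bridge protects A, so negative doublets recover exactly."""
        s = inject_artifacts(
            clean_spectrum, [(ref_co2, -0.3, cfg.co2_range, cfg.co2_peak_max)], cfg
        )
        c, _ = co2_contribution(s, ref_co2, cfg)
        assert c == pytest.approx(-0.3, abs=0.02)

    def test_negative_wv_sign_and_region_scale(self, clean_spectrum, ref_wv, cfg):
        """Downward water-vapor combs keep their sign and region amplitude.

        Nothing shields [3780, 3920] from the global hull, so the dips
        inflate the area normaliser and |c_wv| is attenuated; the region-level
        amplitude (before area normalisation) is still recovered to ~1%.
        """
        from mirqc.preprocess import extract_peak, total_area

        alpha = -0.3
        a_clean = total_area(clean_spectrum, cfg)
        s = inject_artifacts(
            clean_spectrum, [(ref_wv, alpha, cfg.wv_range, cfg.wv_peak_max)], cfg
        )
        c, _ = water_vapor_contribution(s, ref_wv, cfg)
        assert c < 0
        query = extract_peak(s, *cfg.wv_range, cfg.wv_peak_max).intensities
        x = extract_peak(ref_wv.spectrum, *cfg.wv_range, cfg.wv_peak_max).intensities
        x = x / total_area(ref_wv.spectrum, cfg)
        beta_hat = float(np.sum(query * x) / np.sum(x * x))
        beta_true = alpha * a_clean / (1 - alpha * float(np.sum(x)))
        assert beta_hat == pytest.approx(beta_true, rel=0.02)

    def test_linearity_in_alpha(self, clean_spectrum, ref_wv, cfg):
        alphas = np.array([0.25, 0.5, 1.0, 2.0])
        cs = []
        for a in alphas:
            s = inject_artifacts(
                clean_spectrum, [(ref_wv, a, cfg.wv_range, cfg.wv_peak_max)], cfg
            )
            cs.append(water_vapor_contribution(s, ref_wv, cfg)[0])
        slope, _ = linear_fit(alphas, np.asarray(cs))
        assert slope == pytest.approx(1.0, abs=0.05)
        assert np.all(np.diff(cs) > 0)

    def test_missing_coverage_raises(self, ref_wv, cfg, clean_spectrum):
        short = clip(clean_spectrum, 650, 3750)  # ATR-like range end
        with pytest.raises(CoverageError):
            water_vapor_contribution(short, ref_wv, cfg)

    def test_null_estimates_unbiased_and_small(self, ref_co2, cfg):
        """Without injected CO2, c is unbiased and negligible vs real artifacts.

        The classical OLS slope se understates the null sampling sd (the
        rubberband-corrected residuals are correlated), so the check is on
        the estimates themselves, not on se-based coverage.
        """
        cs = []
        for i in range(40):
            s, _ = simulate_spectrum(ArtifactTruth(noise_sd=2e-4, seed=500 + i))
            c, _ = co2_contribution(s, ref_co2, cfg)
            cs.append(c)
        cs = np.asarray(cs)
        assert np.abs(cs).max() < 1e-4
        assert abs(cs.mean()) < 3 * cs.std() / np.sqrt(cs.size)


class TestNoiseLevel:
    def test_smooth_spectrum_noise_free(self, clean_spectrum, cfg):
        assert noise_level(clean_spectrum, cfg) < 1e-12

    def test_mean_noise_increases_with_sd(self, cfg):
        grid = {1e-4: [], 3e-4: [], 1e-3: []}
        for sd, acc in grid.items():
            for i in range(20):
                s, _ = simulate_spectrum(ArtifactTruth(noise_sd=sd, seed=i))
                acc.append(noise_level(s, cfg))
        means = [np.mean(grid[sd]) for sd in (1e-4, 3e-4, 1e-3)]
        assert means[0] < means[1] < means[2]

    def test_invariant_under_uniform_scaling(self, cfg):
        s, _ = simulate_spectrum(ArtifactTruth(noise_sd=3e-4, seed=42))
        doubled = s.with_intensities(2.0 * s.intensities)
        assert noise_level(doubled, cfg) == pytest.approx(
            noise_level(s, cfg), rel=1e-10
        )

    def test_invariant_under_affine_baseline(self, cfg):
        s, _ = simulate_spectrum(ArtifactTruth(noise_sd=3e-4, seed=43))
        w = s.wavenumbers
        shifted = s.with_intensities(s.intensities + 0.3 - 4e-5 * w)
        assert noise_level(shifted, cfg) == pytest.approx(
            noise_level(s, cfg), abs=1e-8 * noise_level(s, cfg) + 1e-16
        )


class TestQcReport:
    def test_columns_and_row_count(self, ref_wv, ref_co2, cfg):
        spectra = [
            simulate_spectrum(ArtifactTruth(seed=i), id=f"s{i}")[0] for i in range(3)
        ]
        from mirqc import SpectraBatch

        rep = qc_report(SpectraBatch(spectra), ref_wv, ref_co2, cfg)
        assert list(rep.columns) == REPORT_COLUMNS
        assert len(rep) == 3
        assert list(rep["id"]) == ["s0", "s1", "s2"]

    def test_missing_coverage_becomes_flagged_empty_cell(self, ref_wv, ref_co2, cfg):
        s, _ = simulate_spectrum()
        short = clip(s, 650, 3750)
        from mirqc import SpectraBatch

        rep = qc_report(SpectraBatch([short]), ref_wv, ref_co2, cfg)
        row = rep.iloc[0]
        assert np.isnan(row["mir_water_vapor_contribution_relative"])
        assert "c_wv" in row["flags"]
        assert "partial coverage" in row["flags"]
        # CO2 window is still covered
        assert np.isfinite(row["mir_co2_contribution_relative"])

    def test_humification_index_column_optional(self, ref_wv, ref_co2, cfg):
        from mirqc import SpectraBatch

        s, _ = simulate_spectrum()
        rep = qc_report(SpectraBatch([s]), ref_wv, ref_co2, cfg, include_hi=True)
        assert "hi_1630_1090" in rep.columns
        assert np.isfinite(rep.iloc[0]["hi_1630_1090"])
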