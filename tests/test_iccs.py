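import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from replisort import (
    ChannelImage,
    CountMask,
    GaussianFit,
    IccsSettings,
    coloc_fractions,
    fit_gaussian,
    generate_coloc_nucleus,
    iccs_per_nucleus,
    iccs_single,
    masked_correlation,
    radial_profile,
)
from replisort.sorting import NucleusRecord

from conftest import brute_force_masked_correlation, disk_mask


class TestMaskedCorrelation:
    @pytest.mark.parametrize("shape,max_lag,seed", [
        ((16, 16), 4, 0),
        ((24, 20), 6, 1),
        ((32, 32), 8, 2),
    ])
    def test_matches_nested_loop_oracle(self, shape, max_lag, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(1, 10, shape)
        b = rng.uniform(1, 10, shape)
        mask = np.ones(shape, bool)
        mask[rng.uniform(size=shape) < 0.2] = False
        if mask.sum() < 100:
            mask[:] = True
        cf = masked_correlation(a, b, mask, max_lag, min_overlap=1)
        oracle, counts = brute_force_masked_correlation(a, b, mask, max_lag)
        np.testing.assert_array_equal(cf.overlap_counts, counts)
        rel = np.abs(cf.values - oracle) / np.maximum(np.abs(oracle), 1e-30)
        tol = 1e-10 if shape == (16, 16) else 1e-8
        assert np.nanmax(rel) < tol

    def test_zero_lag_is_variance_over_mean_squared(self, rng):
        a = rng.uniform(1, 5, (20, 20))
        mask = disk_mask((20, 20), (10, 10), 9)
        cf = masked_correlation(a, a, mask, 3, min_overlap=1, channel_pair="11")
        expected = a[mask].var() / a[mask].mean() ** 2
        assert cf.zero_lag == pytest.approx(expected, rel=1e-12)

    def test_acf_symmetric_under_lag_negation(self, rng):
        a = rng.uniform(1, 5, (32, 32))
        mask = np.ones((32, 32), bool)
        cf = masked_correlation(a, a, mask, 5, min_overlap=1, channel_pair="11")
        np.testing.assert_allclose(cf.values, cf.values[::-1, ::-1], rtol=1e-10)

    def test_pearson_identity_at_zero_lag(self, rng):
        """Symmetric zero-lag ratio equals the Pearson coefficient exactly."""
        a = rng.uniform(1, 10, (30, 30))
        b = 0.4 * a + rng.uniform(1, 10, (30, 30))
        mask = disk_mask((30, 30), (15, 15), 13)
        g11 = masked_correlation(a, a, mask, 2, 1).zero_lag
        g22 = masked_correlation(b, b, mask, 2, 1).zero_lag
        g12 = masked_correlation(a, b, mask, 2, 1).zero_lag
        f = g12 / np.sqrt(g11 * g22)
        pearson = sps.pearsonr(a[mask], b[mask]).statistic
        assert f == pytest.approx(pearson, abs=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.uniform(1, 10, (24, 24))
        b = rng.uniform(1, 10, (24, 24))
        mask = np.ones((24, 24), bool)
        g = masked_correlation(a, b, mask, 4, 1).values
        g_scaled = masked_correlation(7.3 * a, 0.2 * b, mask, 4, 1).values
        np.testing.assert_allclose(g_scaled, g, rtol=1e-9)

    def test_degenerate_and_error_cases(self, rng):
        mask = np.ones((16, 16), bool)
        ok = rng.uniform(1, 2, (16, 16))
        with pytest.raises(ValueError, match="degenerate"):
            masked_correlation(np.full((16, 16), 3.0), ok, mask, 2, 1)
        with pytest.raises(ValueError, match="zero mean"):
            zero_mean = np.zeros((16, 16))
            zero_mean[0, 0] = 0.0
            masked_correlation(zero_mean, ok, mask, 2, 1)
        with pytest.raises(ValueError, match="100 pixels"):
            small = np.zeros((16, 16), bool)
            small[:5, :5] = True
            masked_correlation(ok, ok, small, 2, 1)
        with pytest.raises(ValueError, match="shape"):
            masked_correlation(ok, ok[:8], mask, 2, 1)

    def test_low_overlap_lags_missing(self, rng):
        a = rng.uniform(1, 5, (20, 20))
        mask = np.ones((20, 20), bool)
        cf = masked_correlation(a, a, mask, 6, min_overlap=300)
        # at lag (6, 6) the overlap is 14*14 = 196 < 300
        assert np.isnan(cf.values[-1, -1])
        assert np.isfinite(cf.values[6, 6])  # lag (0, 0): overlap 400


class TestRadialProfile:
    def test_bin_count_and_zero_lag_exclusion(self, rng):
        a = rng.uniform(1, 5, (40, 40))
        cf = masked_correlation(a, a, np.ones((40, 40), bool), 8, 1)
        profile = radial_profile(cf)
        assert list(profile["r"]) == list(range(1, 9))
        assert (profile["n_points"] > 0).all()

    def test_isotropic_profile_matches_axis_slice(self):
        L = 8
        yy, xx = np.mgrid[-L:L + 1, -L:L + 1]
        g = 0.5 * np.exp(-(yy**2 + xx**2) / 9.0) + 0.01
        from replisort.iccs import CorrelationFunction

        cf = CorrelationFunction(g, np.full_like(g, 1000, dtype=int), "11", L)
        profile = radial_profile(cf)
        axis = g[L, L + 1:]  # single-axis slice at r = 1..L
        # binning mixes radii: agree loosely with the axis values
        assert np.all(np.abs(profile["g_mean"].to_numpy() - axis) < 0.05)

    def test_all_missing_bin_reported_empty(self, rng):
        a = rng.uniform(1, 5, (24, 24))
        cf = masked_correlation(a, a, np.ones((24, 24), bool), 8, min_overlap=1)
        cf.values[:, :] = np.nan
        profile = radial_profile(cf)
        assert (profile["n_points"] == 0).all()
        assert profile["g_mean"].isna().all()


def gaussian_profile(b, w, ginf, max_lag=12, n_points=100):
    r = np.arange(1, max_lag + 1, dtype=float)
    return pd.DataFrame({"r": r, "g_mean": b * np.exp(-r**2 / w**2) + ginf,
                         "n_points": n_points})


class TestGaussianFit:
    def test_exact_recovery_of_noiseless_profile(self):
        fit = fit_gaussian(gaussian_profile(0.4, 3.0, 0.01), 12)
        assert fit.converged
        assert fit.amplitude_b == pytest.approx(0.4, abs=1e-6)
        assert fit.width_w == pytest.approx(3.0, abs=1e-6)
        assert fit.offset_ginf == pytest.approx(0.01, abs=1e-6)

    def test_amplitude_error_under_noise(self):
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            profile = gaussian_profile(0.4, 3.0, 0.01)
            profile["g_mean"] += rng.normal(0, 0.004, len(profile))  # ~1% of G(0)
            fit = fit_gaussian(profile, 12)
            errors.append(abs(fit.amplitude_b - 0.4))
        assert np.median(errors) < 0.02

    def test_flat_profile_gives_zero_amplitude(self):
        fit = fit_gaussian(gaussian_profile(0.0, 3.0, 0.01), 12)
        assert abs(fit.amplitude_b) < 1e-3

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="5 usable"):
            fit_gaussian(gaussian_profile(0.4, 3.0, 0.01, max_lag=3), 3)


def _fit(b):
    return GaussianFit(b, 3.0, 0.0, 0.0, True)


class TestColocFractions:
    def test_identical_channels_give_unity(self):
        for convention in ("asymmetric", "pearson"):
            res = coloc_fractions(_fit(0.3), _fit(0.3), _fit(0.3), convention)
            assert res.f1 == pytest.approx(1.0) and res.f2 == pytest.approx(1.0)

    def test_zero_cross_amplitude_gives_zero(self):
        res = coloc_fractions(_fit(0.2), _fit(0.1), _fit(0.0))
        assert res.f1 == 0.0 and res.f2 == 0.0

    def test_asymmetric_and_pearson_arithmetic(self):
        res = coloc_fractions(_fit(0.2), _fit(0.1), _fit(0.05))
        assert res.f1 == pytest.approx(0.5)
        assert res.f2 == pytest.approx(0.25)
        res_p = coloc_fractions(_fit(0.2), _fit(0.1), _fit(0.05), "pearson")
        assert res_p.f1 == pytest.approx(0.05 / np.sqrt(0.02))
        assert res_p.f1 == res_p.f2 == pytest.approx(0.3536, abs=1e-4)

    def test_negative_cross_amplitude_not_clamped(self):
        res = coloc_fractions(_fit(0.2), _fit(0.1), _fit(-0.05))
        assert res.f1 == pytest.approx(-0.5)

    def test_bad_acf_flagged(self):
        res = coloc_fractions(_fit(-0.1), _fit(0.1), _fit(0.05))
        assert np.isnan(res.f1) and "bad-acf" in res.qc_flags

    def test_failed_fit_propagates_missing(self):
        bad = GaussianFit(np.nan, np.nan, np.nan, np.nan, False)
        res = coloc_fractions(_fit(0.2), bad, _fit(0.05))
        assert np.isnan(res.f1) and "fit-failed" in res.qc_flags


class TestIccsOnSyntheticNuclei:
    def test_identical_channels_f1_unity(self):
        a, _, mask = generate_coloc_nucleus(n_foci=50, phi=0.0, radius=40,
                                            noise=False, seed=1)
        res = iccs_single(a, a, mask)
        assert res.f1 == pytest.approx(1.0, abs=0.05)
        assert res.f2 == pytest.approx(1.0, abs=0.05)

    def test_translation_shifts_ccf_peak_and_lowers_amplitude(self):
        a, _, mask = generate_coloc_nucleus(n_foci=60, phi=0.0, radius=40,
                                            noise=False, seed=3)
        amplitudes = []
        for shift in (0, 3, 6):
            b = np.roll(a, shift, axis=1)
            cf = masked_correlation(a, b, mask, 12, min_overlap=50)
            L = 12
            peak = np.unravel_index(np.nanargmax(cf.values), cf.values.shape)
            assert peak == (L, L + shift)
            fit = fit_gaussian(radial_profile(cf), 12)
            amplitudes.append(fit.amplitude_b)
        assert amplitudes[0] > amplitudes[1] > amplitudes[2]

    def test_scale_invariance_of_fractions(self):
        a, b, mask = generate_coloc_nucleus(n_foci=100, phi=0.5, radius=40, seed=5)
        res = iccs_single(a, b, mask)
        res_scaled = iccs_single(3.0 * a, 0.5 * b, mask)
        assert res_scaled.f1 == pytest.approx(res.f1, abs=1e-9)
        assert res_scaled.f2 == pytest.approx(res.f2, abs=1e-9)


class TestIccsPerNucleus:
    def _frame(self, radius=30):
        labels = np.zeros((100, 100), int)
        labels[disk_mask((100, 100), (50, 50), radius)] = 1
        a, b, _ = generate_coloc_nucleus(n_foci=60, phi=1.0, radius=radius, seed=2)
        # embed the nucleus crop into the frame
        img_a = np.full((100, 100), a.mean())
        img_b = np.full((100, 100), b.mean())
        c0 = 50 - a.shape[0] // 2
        img_a[c0:c0 + a.shape[0], c0:c0 + a.shape[1]] = a
        img_b[c0:c0 + b.shape[0], c0:c0 + b.shape[1]] = b
        return (ChannelImage(img_a, channel_role="RF", frame_id="f"),
                ChannelImage(img_b, channel_role="TF", frame_id="f"),
                CountMask(labels))

    def test_s_phase_nuclei_get_fractions(self):
        rf, tf, mask = self._frame()
        rec = NucleusRecord("f", 1, 2821, 500, 500 / 2821, 80.0, phase="EARLY")
        [out] = iccs_per_nucleus(rf, tf, mask, [rec],
                                 IccsSettings(max_lag_px=16, min_overlap=50))
        assert np.isfinite(out.f1)

    def test_g1g2_skipped(self):
        rf, tf, mask = self._frame()
        rec = NucleusRecord("f", 1, 2821, 0, 0.0, 0.0, phase="G1G2")
        [out] = iccs_per_nucleus(rf, tf, mask, [rec])
        assert np.isnan(out.f1) and not out.qc_flags

    def test_insufficient_foci_flagged(self):
        rf, tf, mask = self._frame()
        rec = NucleusRecord("f", 1, 2821, 5, 5 / 2821, 40.0, phase="EARLY")
        [out] = iccs_per_nucleus(rf, tf, mask, [rec])
        assert np.isnan(out.f1)
        assert "insufficient-foci" in out.qc_flags

    def test_per_nucleus_failure_does_not_abort(self):
        rf, tf, mask = self._frame()
        # constant channel inside the nucleus -> degenerate correlation
        flat = ChannelImage(np.full((100, 100), 5.0), channel_role="TF", frame_id="f")
        rec = NucleusRecord("f", 1, 2821, 500, 500 / 2821, 80.0, phase="MIDDLE")
        [out] = iccs_per_nucleus(rf, flat, mask, [rec])
        assert np.isnan(out.f1)
        assert any(fl.startswith("iccs-error") for fl in out.qc_flags)
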