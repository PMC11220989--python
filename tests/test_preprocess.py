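"""Preprocessing chain: despiking, background, smoothing, baseline, area."""

import numpy as np
import pytest

import ramanscreen as rs
from ramanscreen.preprocess import (
    PreprocessConfig,
    PreprocessError,
    estimate_baseline_poly,
    preprocess_set,
)
from ramanscreen.spectra_io import SpectraValidationError
from ramanscreen.synthetic_cohort import lorentzian

from conftest import make_spectrum


def grid200():
    return rs.WavenumberGrid(np.linspace(400.0, 599.0, 200))


class TestRemoveCosmicRays:
    def test_spike_free_smooth_spectrum_untouched(self):
        x = np.linspace(0, 4 * np.pi, 300)
        s = make_spectrum(100 + 10 * np.sin(x))
        out = rs.remove_cosmic_rays(s, window=5, z=8.0)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_planted_single_spike_removed_neighbours_untouched(self):
        rng = np.random.default_rng(4)
        y = 100 + rng.normal(0, 1.0, 400)
        spiked = y.copy()
        spiked[200] += 50.0  # 50 sigma
        out = rs.remove_cosmic_rays(make_spectrum(spiked), window=5, z=8.0)
        assert abs(out.intensities[200] - spiked[200]) > 40.0
        untouched = np.delete(np.arange(400), 200)
        assert np.max(np.abs(out.intensities[untouched] - spiked[untouched])) < 1e-9
        # replacement bridges the neighbours linearly
        np.testing.assert_allclose(
            out.intensities[200], 0.5 * (y[199] + y[201]), atol=1e-9
        )

    def test_adjacent_spike_pair_bridged_across_run(self):
        rng = np.random.default_rng(5)
        y = 50 + rng.normal(0, 1.0, 300)
        spiked = y.copy()
        spiked[120] += 60.0
        spiked[121] += 55.0
        out = rs.remove_cosmic_rays(make_spectrum(spiked), window=5, z=8.0)
        expect = np.interp([120, 121], [119, 122], [y[119], y[122]])
        np.testing.assert_allclose(out.intensities[[120, 121]], expect, atol=1e-9)
        untouched = np.delete(np.arange(300), [120, 121])
        assert np.max(np.abs(out.intensities[untouched] - spiked[untouched])) < 1e-9

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rs.remove_cosmic_rays(make_spectrum(np.ones(10)), window=4)


class TestBackground:
    def test_subtract_is_elementwise_and_preserves_metadata(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=50), rng.normal(size=50)
        s = make_spectrum(a, subject="p1", group="cancer", session=2, scan=3)
        out = rs.subtract_background(s, make_spectrum(b, subject="bg", group="unknown"))
        np.testing.assert_allclose(out.intensities, a - b)
        assert out.key == ("p1", 2, 3) and out.group == "cancer"

    def test_subtracting_self_gives_zero_and_zero_is_identity(self):
        y = np.random.default_rng(7).normal(size=30)
        s = make_spectrum(y)
        np.testing.assert_allclose(
            rs.subtract_background(s, s).intensities, np.zeros(30), atol=1e-15
        )
        np.testing.assert_allclose(
            rs.subtract_background(s, make_spectrum(np.zeros(30))).intensities, y
        )

    def test_mean_background_matches_pointwise_mean_oracle(self):
        rng = np.random.default_rng(8)
        mats = rng.normal(size=(10, 40))
        out = rs.mean_background([make_spectrum(m, scan=i + 1) for i, m in enumerate(mats)])
        np.testing.assert_allclose(out.intensities, mats.mean(axis=0), atol=1e-12)

    def test_midpoint_of_a_and_3a(self):
        a = np.arange(20.0)
        out = rs.mean_background([make_spectrum(a, scan=1), make_spectrum(3 * a, scan=2)])
        np.testing.assert_allclose(out.intensities, 2 * a)

    def test_empty_background_list_rejected(self):
        with pytest.raises(SpectraValidationError):
            rs.mean_background([])


def dense_awls_oracle(y, lam, max_iter=10, tol=1e-3):
    """Dense normal-equations replica of the iteratively reweighted Whittaker
    smoother: full-matrix construction of W + lam*D'D solved with
    numpy.linalg.solve, weights by the same Cauchy rule on MAD-standardised
    residuals."""
    n = y.size
    d = np.zeros((n - 2, n))
    for i in range(n - 2):
        d[i, i : i + 3] = [1.0, -2.0, 1.0]
    dtd = d.T @ d
    w = np.ones(n)

    def solve(w):
        return np.linalg.solve(np.diag(w) + lam * dtd, w * y)

    for _ in range(max(1, max_iter)):
        z = solve(w)
        r = y - z
        mad = np.median(np.abs(r - np.median(r)))
        scale = 1.4826 * mad if mad > 0 else float(np.std(r))
        if scale == 0.0:
            break
        w_new = 1.0 / (1.0 + (r / (2.385 * scale)) ** 2)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return solve(w)


class TestSmoothAWLS:
    def test_zero_lambda_is_identity(self):
        y = np.random.default_rng(9).normal(size=100)
        out = rs.smooth_awls(make_spectrum(y), smooth_lambda=0.0)
        np.testing.assert_array_equal(out.intensities, y)

    def test_constant_spectrum_unchanged(self):
        out = rs.smooth_awls(make_spectrum(np.full(120, 7.0)), smooth_lambda=1e4)
        np.testing.assert_allclose(out.intensities, 7.0, atol=1e-8)

    def test_noisy_sine_matches_dense_solver_and_reduces_rmse(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 2 * np.pi, 200)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.1, x.size)
        out = rs.smooth_awls(make_spectrum(noisy), smooth_lambda=1e3).intensities
        oracle = dense_awls_oracle(noisy, 1e3)
        assert np.max(np.abs(out - oracle)) < 1e-8
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_out < rmse_in

    @pytest.mark.parametrize("lam", [10.0, 1e3, 1e5])
    def test_dense_oracle_equivalence_across_penalties(self, lam):
        rng = np.random.default_rng(11)
        y = rng.normal(size=150).cumsum()
        out = rs.smooth_awls(make_spectrum(y), smooth_lambda=lam).intensities
        assert np.max(np.abs(out - dense_awls_oracle(y, lam))) < 1e-8

    def test_nonfinite_input_rejected(self):
        y = np.ones(50)
        s = make_spectrum(y)
        s.intensities[3] = np.inf  # bypass constructor validation deliberately
        with pytest.raises(SpectraValidationError):
            rs.smooth_awls(s)


class TestBaseline:
    def test_pure_polynomial_input_flattened_to_zero(self):
        x = np.linspace(-1, 1, 300)
        y = 5.0 + 3.0 * x - 2.0 * x**2 + 0.5 * x**4
        out = rs.correct_baseline_poly(make_spectrum(y), order=5)
        assert np.max(np.abs(out.intensities)) < 1e-6

    def test_baseline_free_peaks_survive_at_apex(self):
        g = grid200()
        x = g.values
        y = 100 * lorentzian(x, 450.0, 3.0) + 80 * lorentzian(x, 550.0, 3.0)
        out = rs.correct_baseline_poly(make_spectrum(y), order=5)
        for center, height in ((450.0, 100.0), (550.0, 80.0)):
            apex = np.argmin(np.abs(x - center))
            assert abs(out.intensities[apex] - y[apex]) / height < 0.05

    def test_planted_quadratic_baseline_recovered_within_5pct(self):
        g = grid200()
        x = g.values
        t = np.linspace(-1, 1, x.size)
        baseline = 50.0 + 20.0 * t - 30.0 * t**2
        peaks = 200 * lorentzian(x, 460.0, 4.0) + 150 * lorentzian(x, 540.0, 4.0)
        out = rs.correct_baseline_poly(make_spectrum(peaks + baseline), order=5)
        for center, height in ((460.0, 200.0), (540.0, 150.0)):
            apex = np.argmin(np.abs(x - center))
            assert abs(out.intensities[apex] - peaks[apex]) / height < 0.05

    def test_approximate_idempotence(self):
        g = grid200()
        x = g.values
        y = 100 * lorentzian(x, 500.0, 5.0) + 30 + 10 * np.linspace(0, 1, x.size)
        once = rs.correct_baseline_poly(make_spectrum(y), order=5)
        twice = rs.correct_baseline_poly(once, order=5)
        scale = np.ptp(y)
        assert np.max(np.abs(twice.intensities - once.intensities)) < 1e-3 * scale

    def test_order_must_be_below_grid_length(self):
        with pytest.raises(ValueError):
            estimate_baseline_poly(np.ones(4), order=5)


class TestNormalize:
    def test_unit_area_within_1e12(self):
        g = grid200()
        y = np.abs(np.random.default_rng(12).normal(10, 2, len(g))) + 1.0
        out = rs.normalize_total_area(make_spectrum(y), g.values)
        assert abs(np.trapezoid(out.intensities, g.values) - 1.0) < 1e-12

    def test_scale_invariance_and_idempotence(self):
        g = grid200()
        y = np.abs(np.random.default_rng(13).normal(10, 2, len(g))) + 1.0
        a = rs.normalize_total_area(make_spectrum(y), g.values)
        b = rs.normalize_total_area(make_spectrum(17.0 * y), g.values)
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)
        again = rs.normalize_total_area(a, g.values)
        np.testing.assert_allclose(again.intensities, a.intensities, rtol=1e-12)

    def test_all_ones_becomes_uniform_density(self):
        grid = rs.default_grid(step=4.0)  # span 1400 cm^-1
        out = rs.normalize_total_area(make_spectrum(np.ones(len(grid))), grid.values)
        np.testing.assert_allclose(out.intensities, 1.0 / 1400.0, rtol=1e-12)

    def test_nonpositive_area_raises(self):
        g = grid200()
        with pytest.raises(PreprocessError, match="area"):
            rs.normalize_total_area(make_spectrum(-np.ones(len(g))), g.values)


class TestFullChain:
    def test_empty_set_passes_through(self, coarse_grid):
        out = preprocess_set(rs.SpectrumSet(coarse_grid, []))
        assert len(out) == 0

    def test_chain_preserves_count_metadata_and_unit_area(self, tiny_cohort, coarse_grid):
        cfg, sset, _ = tiny_cohort
        bg = rs.mean_background(
            rs.synthetic_cohort.generate_background_scans(cfg, coarse_grid)
        )
        out = preprocess_set(sset, bg)
        assert len(out) == len(sset)
        assert [s.key for s in out] == [s.key for s in sset]
        assert [s.group for s in out] == [s.group for s in sset]
        areas = [np.trapezoid(s.intensities, coarse_grid.values) for s in out]
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_null_cohort_group_means_agree_within_pooled_se(self, coarse_grid):
        # spectrum-level SEs presume independent spectra, so the subject
        # random effect (which correlates the 15 replicate scans) is off here
        cfg = rs.null_config(
            rs.CohortConfig(
                n_per_group={"healthy": 6, "benign": 0, "cancer": 6},
                seed=31,
                noise_sd=5.0,
                subject_effect_sd=0.0,
            )
        )
        sset, _ = rs.generate_cohort(cfg, coarse_grid)
        bg = rs.mean_background(
            rs.synthetic_cohort.generate_background_scans(cfg, coarse_grid)
        )
        out = preprocess_set(sset, bg)
        a = out.select_groups(["healthy"]).intensity_matrix()
        b = out.select_groups(["cancer"]).intensity_matrix()
        diff = a.mean(axis=0) - b.mean(axis=0)
        pooled_se = np.sqrt(a.var(axis=0, ddof=1) / a.shape[0] + b.var(axis=0, ddof=1) / b.shape[0])
        frac_within = np.mean(np.abs(diff) <= 2 * pooled_se)
        assert frac_within >= 0.95
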