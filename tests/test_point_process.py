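"""Unit and property tests for the spatial null-model simulators."""

import numpy as np
import pytest
from scipy import stats

from forestnets import (ConvergenceError, CrownDistribution, DataError,
                        MarkedPattern, NullModelConfig, ParameterError, Window,
                        assign_crown_radii, estimate_intensity,
                        fit_crown_gamma, simulate, simulate_csr,
                        simulate_hardcore, simulate_matern, simulate_strauss,
                        simulate_thomas)
from forestnets.point_process import GAUSS_SCALE_FACTOR


class TestWindowAndConfig:
    def test_degenerate_window_rejected(self):
        with pytest.raises(ParameterError):
            Window(0, 0, 0, 10)

    def test_window_area(self):
        assert Window(0, 200, 0, 200).area == 40000.0

    @pytest.mark.parametrize("bad", [
        dict(kappa=0.0), dict(kappa=-1.0), dict(p=1.5),
        dict(model="MATERN", mu=0.0), dict(model="THOMAS", r_d=-2.0),
        dict(model="STRAUSS", r_g=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            NullModelConfig(**bad)

    def test_unknown_model_rejected(self):
        with pytest.raises(ParameterError):
            NullModelConfig(model="POISSON_FOREST")


class TestCSR:
    def test_counts_match_poisson_mean(self, window):
        """Mean count over 199 replicates within 3 standard errors of kappa*|W|."""
        cfg = NullModelConfig(model="CSR", kappa=0.015)
        counts = [simulate_csr(cfg, window, seed=s).n for s in range(199)]
        expected = 0.015 * window.area  # 600
        se = np.sqrt(expected / 199)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_all_points_inside_window(self, window):
        pat = simulate_csr(NullModelConfig(model="CSR"), window, seed=3)
        assert window.contains(pat.x, pat.y).all()

    def test_same_seed_is_bit_identical(self, window):
        cfg = NullModelConfig(model="CSR")
        a = simulate_csr(cfg, window, seed=11)
        b = simulate_csr(cfg, window, seed=11)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_wrong_model_config_rejected(self, window):
        with pytest.raises(ParameterError):
            simulate_csr(NullModelConfig(model="MATERN"), window)


class TestClusterProcesses:
    def test_offspring_within_dispersal_radius_of_parent(self, window):
        cfg = NullModelConfig(model="MATERN")
        pat = simulate_matern(cfg, window, seed=5)
        d = np.hypot(pat.x - pat.parents[pat.parent_index, 0],
                     pat.y - pat.parents[pat.parent_index, 1])
        assert np.all(d <= cfg.r_d + 1e-12)

    def test_matern_mean_count_matches_kappa(self, window):
        """Tree intensity is kappa itself: parents are thinned to kappa/mu."""
        cfg = NullModelConfig(model="MATERN", kappa=0.015, mu=3.0)
        counts = [simulate_matern(cfg, window, seed=s).n for s in range(60)]
        expected = 0.015 * window.area  # 600
        # Monte-Carlo oracle: var(N) for a Poisson cluster process is
        # (kappa/mu)*|W|*(mu + mu^2) plus edge effects; 5 sigma is generous
        se = np.sqrt(0.005 * window.area * (3 + 9) / 60)
        assert abs(np.mean(counts) - expected) < 5 * se

    def test_matern_parent_intensity_flag(self, window):
        """The alternative reading: kappa counts parents, trees at kappa*mu."""
        cfg = NullModelConfig(model="MATERN", kappa=0.015, mu=3.0,
                              kappa_is_parent=True)
        counts = [simulate_matern(cfg, window, seed=s).n for s in range(60)]
        assert abs(np.mean(counts) - 1800) < 120

    def test_matern_rd_zero_limit_collapses_to_parents(self, window):
        cfg = NullModelConfig(model="MATERN", r_d=1e-9)
        pat = simulate_matern(cfg, window, seed=2)
        d = np.hypot(pat.x - pat.parents[pat.parent_index, 0],
                     pat.y - pat.parents[pat.parent_index, 1])
        assert np.all(d < 1e-8)

    def test_thomas_sigma_zero_limit_collapses_to_parents(self, window):
        cfg = NullModelConfig(model="THOMAS", sigma=0.0)
        pat = simulate_thomas(cfg, window, seed=2)
        d = np.hypot(pat.x - pat.parents[pat.parent_index, 0],
                     pat.y - pat.parents[pat.parent_index, 1])
        assert np.all(d == 0.0)

    def test_thomas_displacement_sd_matches_sigma(self):
        """Empirical per-axis offspring displacement SD ~ sigma (MC oracle)."""
        big = Window(0, 500, 0, 500)
        cfg = NullModelConfig(model="THOMAS", kappa=0.01, mu=5.0)
        pat = simulate_thomas(cfg, big, seed=9)
        dx = pat.x - pat.parents[pat.parent_index, 0]
        sd = np.std(dx)
        sigma = cfg.gauss_sigma
        assert sigma == pytest.approx(5.0 * GAUSS_SCALE_FACTOR)
        # interior points only are retained, slight truncation: 5% tolerance
        assert sd == pytest.approx(sigma, rel=0.05)

    def test_thomas_mean_count(self, window):
        cfg = NullModelConfig(model="THOMAS")
        counts = [simulate_thomas(cfg, window, seed=s).n for s in range(60)]
        se = np.sqrt(0.005 * window.area * 12 / 60)
        assert abs(np.mean(counts) - 600) < 5 * se


class TestGibbsProcesses:
    def test_hardcore_minimum_distance_every_replicate(self, window):
        cfg = NullModelConfig(model="HARDCORE", r_g=4.0)
        for s in range(10):
            pat = simulate_hardcore(cfg, window, seed=s)
            assert pat.min_pairwise_distance() >= 4.0

    def test_hardcore_fixed_n_count_and_distance(self, window):
        cfg = NullModelConfig(model="HARDCORE", r_g=4.0, fixed_n=True)
        pat = simulate_hardcore(cfg, window, seed=1)
        assert pat.n == 600
        assert pat.min_pairwise_distance() >= 4.0

    def test_hardcore_two_points_small_window(self):
        tiny = Window(0, 30, 0, 30)
        cfg = NullModelConfig(model="HARDCORE", kappa=2 / 900, r_g=4.0, fixed_n=True)
        pat = simulate_hardcore(cfg, tiny, seed=0)
        assert pat.n == 2
        assert pat.min_pairwise_distance() >= 4.0

    def test_hardcore_infeasible_packing_raises(self):
        tiny = Window(0, 10, 0, 10)
        cfg = NullModelConfig(model="HARDCORE", kappa=1.0, r_g=4.0, fixed_n=True)
        with pytest.raises((ConvergenceError, ParameterError)):
            simulate_hardcore(cfg, tiny, seed=0)

    def test_strauss_p0_is_hardcore(self, window):
        cfg = NullModelConfig(model="STRAUSS", p=0.0, r_g=4.0)
        for s in range(5):
            pat = simulate_strauss(cfg, window, seed=s)
            assert pat.min_pairwise_distance() >= 4.0

    def test_strauss_interpolates_between_hardcore_and_csr(self, window):
        """Close-pair count at p=0.5 sits strictly between HC (0) and CSR."""

        def close_pairs(pat, r):
            from scipy.spatial import cKDTree

            return len(cKDTree(pat.coords).query_pairs(r))

        csr_pairs = np.mean([
            close_pairs(simulate_csr(NullModelConfig(model="CSR"), window, seed=s), 4.0)
            for s in range(10)])
        str_pairs = np.mean([
            close_pairs(simulate_strauss(NullModelConfig(model="STRAUSS", p=0.5), window,
                                         seed=s), 4.0)
            for s in range(10)])
        assert 0.0 < str_pairs < csr_pairs

    def test_strauss_p1_realized_intensity_near_kappa(self, window):
        """With no inhibition the chain targets a plain Poisson at kappa."""
        cfg = NullModelConfig(model="STRAUSS", p=1.0)
        counts = [simulate_strauss(cfg, window, seed=s).n for s in range(20)]
        assert abs(np.mean(counts) - 600) < 5 * np.sqrt(600 / 20)

    def test_gibbs_reproducible(self, window):
        cfg = NullModelConfig(model="STRAUSS")
        a = simulate_strauss(cfg, window, seed=4)
        b = simulate_strauss(cfg, window, seed=4)
        np.testing.assert_array_equal(a.x, b.x)


class TestCrownMarks:
    def test_uniform_labels_in_range(self, window):
        pat = simulate_csr(NullModelConfig(model="CSR"), window, seed=0)
        lab = assign_crown_radii(pat, CrownDistribution(lo=2.0, hi=5.0), seed=1)
        assert lab.radii.min() >= 2.0 and lab.radii.max() <= 5.0
        assert lab.n == pat.n
        np.testing.assert_array_equal(lab.x, pat.x)  # order unchanged

    def test_nearly_degenerate_uniform(self, window):
        pat = simulate_csr(NullModelConfig(model="CSR"), window, seed=0)
        lab = assign_crown_radii(pat, CrownDistribution(lo=3.0, hi=3.0 + 1e-9), seed=1)
        np.testing.assert_allclose(lab.radii, 3.0, atol=1e-8)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ParameterError):
            CrownDistribution(lo=5.0, hi=2.0)
        with pytest.raises(ParameterError):
            CrownDistribution(kind="gamma", shape=-1.0, rate=2.0)

    def test_gamma_fit_recovers_parameters(self):
        """MLE consistency: shape of Gamma(4, rate 2) recovered within 10%."""
        rng = np.random.default_rng(1)
        sample = rng.gamma(shape=4.0, scale=0.5, size=5000)
        fit = fit_crown_gamma(sample)
        assert fit.shape == pytest.approx(4.0, rel=0.1)
        assert fit.rate == pytest.approx(2.0, rel=0.1)

    def test_gamma_fit_exponential_data_gives_shape_one(self):
        rng = np.random.default_rng(2)
        sample = rng.exponential(scale=2.0, size=5000)
        fit = fit_crown_gamma(sample)
        assert fit.shape == pytest.approx(1.0, rel=0.1)

    def test_gamma_fit_round_trip(self):
        """Fit -> sample -> refit recovers the first fit within a loose CI."""
        rng = np.random.default_rng(3)
        first = fit_crown_gamma(rng.gamma(6.0, 0.5, size=3000))
        resample = stats.gamma.rvs(first.shape, scale=1.0 / first.rate, size=3000,
                                   random_state=4)
        second = fit_crown_gamma(resample)
        assert second.shape == pytest.approx(first.shape, rel=0.15)
        assert second.rate == pytest.approx(first.rate, rel=0.15)

    def test_gamma_fit_rejects_bad_data(self):
        with pytest.raises(DataError):
            fit_crown_gamma([1.0, 2.0, 3.0])  # too few
        with pytest.raises(DataError):
            fit_crown_gamma([1.0] * 20)  # constant
        with pytest.raises(DataError):
            fit_crown_gamma([1.0] * 10 + [-2.0])  # non-positive


class TestIntensity:
    def test_la_selva_plot_density(self):
        win = Window(0, 100, 0, 100)
        rng = np.random.default_rng(0)
        pat = MarkedPattern(rng.uniform(0, 100, 271), rng.uniform(0, 100, 271), win)
        assert estimate_intensity(pat) == pytest.approx(0.0271)

    @pytest.mark.parametrize("n,side,expected", [(600, 200.0, 0.015),
                                                 (600, 400.0, 0.00375)])
    def test_density_scaling(self, n, side, expected):
        win = Window(0, side, 0, side)
        rng = np.random.default_rng(1)
        pat = MarkedPattern(rng.uniform(0, side, n), rng.uniform(0, side, n), win)
        assert estimate_intensity(pat) == pytest.approx(expected)

    def test_empty_pattern_warns_and_returns_zero(self, window):
        pat = MarkedPattern(np.empty(0), np.empty(0), window)
        with pytest.warns(UserWarning):
            assert estimate_intensity(pat) == 0.0


def test_dispatcher_covers_all_models(window):
    for name in ("CSR", "MATERN", "THOMAS", "HARDCORE", "STRAUSS"):
        pat = simulate(NullModelConfig(model=name), window, seed=0)
        assert pat.provenance == name
        assert window.contains(pat.x, pat.y).all()
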