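"""CTCRW filtering, imputation, gridding and distance regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from penguinforage import movement as mv


def dense_ctcrw_loglik(times, x_obs, y_obs, beta, sigma, tau):
    """Brute-force oracle: assemble the full joint Gaussian of observed
    positions by propagating the state covariance recursion, then evaluate
    the multivariate-normal density directly."""
    n = len(times)
    ll = 0.0
    for obs in (x_obs, y_obs):
        covs = np.zeros((n, n, 2, 2))
        covs[0, 0] = np.diag([mv._INIT_POS_SD**2, sigma**2 / (2 * beta)])
        for k in range(1, n):
            F, Q = mv.iou_transition(beta, sigma, times[k] - times[k - 1])
            covs[k, k] = F @ covs[k - 1, k - 1] @ F.T + Q
            for j in range(k):
                covs[k, j] = F @ covs[k - 1, j]
                covs[j, k] = covs[k, j].T
        mu = np.full(n, obs[0])
        Sig = covs[:, :, 0, 0] + np.eye(n) * tau**2
        ll += multivariate_normal.logpdf(obs, mean=mu, cov=Sig)
    return ll


def _toy_track(seed=0, n=5, dt=200.0, beta=1 / 300, sigma=0.07, tau=25.0):
    rng = np.random.default_rng(seed)
    times = np.arange(n) * dt
    return times, mv.simulate_ctcrw_track(times, beta, sigma, tau, rng)


class TestKalmanOracle:
    @pytest.mark.parametrize(
        "beta,sigma,tau",
        [(1 / 300, 0.07, 25.0), (1 / 100, 0.2, 10.0), (1 / 1000, 0.01, 50.0)],
    )
    def test_filter_equals_dense_gaussian(self, beta, sigma, tau):
        """Kalman likelihood ≡ joint-Gaussian oracle on ≤6-fix tracks (1e-6)."""
        for seed, n in ((0, 5), (1, 6), (2, 4)):
            times, tr = _toy_track(seed, n=n)
            kf = mv.ctcrw_loglik([(times, tr.x_obs.values, tr.y_obs.values)], beta, sigma, tau)
            dense = dense_ctcrw_loglik(times, tr.x_obs.values, tr.y_obs.values, beta, sigma, tau)
            assert kf == pytest.approx(dense, abs=1e-6)

    def test_degenerate_geometry_gives_zero_sigma(self):
        fx = pd.DataFrame(
            {"time_s": np.arange(8) * 180.0, "x": np.zeros(8), "y": np.zeros(8)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mv.fit_ctcrw(fx, estimate_meas_err=False, meas_err_sd=25.0)
        assert fit.sigma < 1e-3

    def test_parameter_recovery(self):
        """(β, σ, τ) recovered within 15% from a batch of simulated trips."""
        rng = np.random.default_rng(10)
        frames = []
        for k in range(15):
            tt = np.arange(0, 17460.0, 180.0)
            trk = mv.simulate_ctcrw_track(tt, 1 / 300, 0.065, 25.0, rng)
            trk["trip"] = k
            frames.append(trk)
        fx = pd.concat(frames)[["time_s", "x_obs", "y_obs", "trip"]].rename(
            columns={"x_obs": "x", "y_obs": "y"}
        )
        fit = mv.fit_ctcrw(fx, estimate_meas_err=True, n_starts=1)
        assert fit.beta == pytest.approx(1 / 300, rel=0.15)
        assert fit.sigma == pytest.approx(0.065, rel=0.15)
        assert fit.meas_err_sd == pytest.approx(25.0, rel=0.15)
        assert np.isfinite(fit.log_likelihood)

    def test_too_few_fixes_errors(self):
        fx = pd.DataFrame({"time_s": [0.0, 180.0], "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="4 fixes"):
            mv.fit_ctcrw(fx)


class TestImputation:
    @staticmethod
    def _fit(seed=3, n=21, tau=25.0):
        times, tr = _toy_track(seed, n=n, dt=180.0, tau=tau)
        return mv.CTCRWFit(
            beta=1 / 300, sigma=0.065, meas_err_sd=tau, log_likelihood=0.0,
            segments=[(times, tr.x_obs.values, tr.y_obs.values)],
        )

    def test_empty_dive_times(self):
        assert len(mv.impute_dive_locations(self._fit(), [], n=10)) == 0

    def test_draws_at_fix_time_with_no_error(self):
        times, tr = _toy_track(4, n=8, dt=180.0)
        fit = mv.CTCRWFit(
            beta=1 / 300, sigma=0.065, meas_err_sd=0.0, log_likelihood=0.0,
            segments=[(times, tr.x.values, tr.y.values)],
        )
        dr = mv.impute_dive_locations(fit, [times[4]], n=30, seed=0)
        assert np.allclose(dr.x, tr.x.values[4], atol=1e-4)

    def test_midgap_spread_exceeds_near_fix_spread(self):
        fit = self._fit(tau=1.0)
        # fixes every 180 s: 810 s is mid-gap, 725 s is 5 s after a fix
        dr = mv.impute_dive_locations(fit, [810.0], n=800, seed=1)
        dr2 = mv.impute_dive_locations(fit, [725.0], n=800, seed=2)
        assert dr.x.std() > dr2.x.std()

    def test_draw_mean_matches_across_seeds(self):
        """Mean of many joint draws is seed-stable (consistency with the
        smoothing distribution)."""
        fit = self._fit()
        a = mv.impute_dive_locations(fit, [450.0], n=3000, seed=5)
        b = mv.impute_dive_locations(fit, [450.0], n=3000, seed=6)
        se = a.x.std() / np.sqrt(3000)
        assert a.x.mean() == pytest.approx(b.x.mean(), abs=6 * se)

    def test_draws_exchangeable_across_seeds(self):
        from scipy.stats import ks_2samp

        fit = self._fit()
        a = mv.impute_dive_locations(fit, [450.0], n=2000, seed=7)
        b = mv.impute_dive_locations(fit, [450.0], n=2000, seed=8)
        assert ks_2samp(a.x, b.x).pvalue > 0.01

    def test_extrapolation_flagged(self):
        fit = self._fit()
        dr = mv.impute_dive_locations(fit, [1e6], n=5, seed=0)
        assert dr.extrapolated.all()


class TestGridDensity:
    @staticmethod
    def _draws(n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "lon": -38.05 + rng.uniform(0, 0.05, n),
                "lat": -54.01 + rng.uniform(0, 0.05, n),
            }
        )

    def test_cell_density_product_formula(self):
        """One cell holding 1% of dives at the reported chick-rearing rates."""
        draws = pd.DataFrame(
            {"lon": [-38.049] * 1 + [-38.02] * 99, "lat": [-54.009] * 100}
        )
        m = mv.grid_dive_density(
            draws, prop_at_sea=0.360, dive_rate_per_h=13.62, pairs=390
        )
        cell = m.cells[(0, 0)]
        assert cell == pytest.approx(0.01 * 780 * 0.360 * 24 * 13.62, rel=1e-9)
        assert cell == pytest.approx(917.9, abs=0.5)

    def test_mass_conservation_exact(self):
        m = mv.grid_dive_density(
            self._draws(), prop_at_sea=0.162, dive_rate_per_h=15.39, pairs=390
        )
        assert m.total() == pytest.approx(780 * 0.162 * 24 * 15.39, rel=1e-12)
        assert m.total() == pytest.approx(46672.3, abs=0.1)

    def test_linear_in_pairs_and_p(self):
        draws = self._draws(seed=1)
        base = mv.grid_dive_density(draws, 0.2, 10.0, 100)
        dbl_pairs = mv.grid_dive_density(draws, 0.2, 10.0, 200)
        dbl_p = mv.grid_dive_density(draws, 0.4, 10.0, 100)
        for k, v in base.cells.items():
            assert dbl_pairs.cells[k] == pytest.approx(2 * v)
            assert dbl_p.cells[k] == pytest.approx(2 * v)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            mv.grid_dive_density(pd.DataFrame(columns=["lon", "lat"]), 0.2, 10.0, 100)

    def test_difference_of_map_with_itself_is_zero(self):
        m = mv.grid_dive_density(self._draws(), 0.2, 10.0, 100)
        d = mv.density_difference(m, m)
        assert all(v == 0 for v in d.cells.values())

    def test_difference_union_semantics(self):
        a = mv.GridDensityMap(0.005, (-38.05, -54.01), {(0, 0): 5.0}, "a")
        b = mv.GridDensityMap(0.005, (-38.05, -54.01), {(1, 1): 3.0}, "b")
        d = mv.density_difference(a, b)
        assert d.cells == {(0, 0): -5.0, (1, 1): 3.0}

    def test_mismatched_grids_error(self):
        a = mv.GridDensityMap(0.005, (-38.05, -54.01), {}, "a")
        b = mv.GridDensityMap(0.01, (-38.05, -54.01), {}, "b")
        with pytest.raises(ValueError):
            mv.density_difference(a, b)


class TestDistanceRegression:
    def test_exact_line_recovered(self):
        t = np.linspace(60, 400, 20)
        d = (1.52 + 0.009 * t) ** 2
        reg = mv.fit_distance_regression(t, d)
        assert reg.intercept == pytest.approx(1.52, abs=1e-9)
        assert reg.slope == pytest.approx(0.009, abs=1e-12)

    def test_noisy_recovery_within_10pc(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(120, 420, 300)
        d = (1.52 + 0.009 * t + rng.normal(0, 0.15, t.size)) ** 2
        reg = mv.fit_distance_regression(t, d)
        assert reg.intercept == pytest.approx(1.52, rel=0.10)
        assert reg.slope == pytest.approx(0.009, rel=0.10)

    def test_predicted_incubation_distance(self):
        reg = mv.DistanceRegression(intercept=1.52, slope=0.009, response="total_distance")
        assert reg.predict(291.0) == pytest.approx(17.1, abs=0.1)

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            mv.fit_distance_regression([100, 100, 100], [1, 2, 3])
        with pytest.raises(ValueError):
            mv.fit_distance_regression([1, 2], [1, 2])


class TestProjection:
    def test_round_trip(self):
        lon = np.array([-38.05, -38.0, -37.9])
        lat = np.array([-54.01, -54.05, -53.95])
        x, y = mv.to_planar(lon, lat, (-38.05, -54.01))
        lon2, lat2 = mv.to_lonlat(x, y, (-38.05, -54.01))
        assert np.allclose(lon, lon2) and np.allclose(lat, lat2)
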