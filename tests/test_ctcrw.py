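"""CTCRW state-space model: discretization, filter, ML fit and smoother."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from mtrack.core_data import ErrorModel
from mtrack.ctcrw import (
    CtcrwParams,
    _ctcrw_mats,
    fit_ctcrw,
    kalman_filter,
    regular_grid,
    rms_error_km,
    smooth_predict,
)
from mtrack.experiments import dense_gaussian_loglik, simulate_ctcrw_obs

from conftest import make_obs


class TestDiscretization:
    def test_zero_lag_is_identity_with_no_noise(self):
        T, Q = _ctcrw_mats(1.3, 7.0, 0.0)
        np.testing.assert_allclose(T, np.eye(2))
        np.testing.assert_allclose(Q, np.zeros((2, 2)))

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            _ctcrw_mats(1.0, 1.0, -0.1)

    @pytest.mark.parametrize("beta,sigma,dt", [(1.0, 1.0, 1.0), (0.3, 5.0, 2.5), (4.0, 0.7, 0.25)])
    def test_covariance_matches_ou_quadrature(self, beta, sigma, dt):
        _, Q = _ctcrw_mats(beta, sigma, dt)
        var_zeta = sigma**2 * quad(lambda s: np.exp(-2 * beta * s), 0, dt)[0]
        var_xi = sigma**2 * quad(
            lambda s: ((1 - np.exp(-beta * (dt - s))) / beta) ** 2, 0, dt
        )[0]
        cov = sigma**2 * quad(
            lambda s: np.exp(-beta * (dt - s)) * (1 - np.exp(-beta * (dt - s))) / beta,
            0, dt,
        )[0]
        assert Q[1, 1] == pytest.approx(var_zeta, abs=1e-8)
        assert Q[0, 0] == pytest.approx(var_xi, abs=1e-8)
        assert Q[0, 1] == pytest.approx(cov, abs=1e-8)

    def test_velocity_variance_reaches_stationary_limit(self):
        beta, sigma = 0.8, 3.0
        _, Q = _ctcrw_mats(beta, sigma, 1e6)
        assert Q[1, 1] == pytest.approx(sigma**2 / (2 * beta), rel=1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CtcrwParams(beta=-1.0)
        with pytest.raises(ValueError):
            CtcrwParams(sigma=0.0)


class TestFilterOracle:
    def test_loglik_matches_dense_gaussian_on_short_tracks(self):
        """Property check: prediction-error decomposition equals the joint
        Gaussian density obtained by explicit state marginalization."""
        rng = np.random.default_rng(1)
        err = ErrorModel()
        for _ in range(40):
            n = int(rng.integers(3, 11))
            t = np.sort(rng.uniform(0, 15, n)); t[0] = 0.0
            lon = 180.0 + rng.normal(0, 0.5, n)
            lat = -30.0 + rng.normal(0, 0.5, n)
            cls = rng.choice(["3", "2", "1", "0", "A", "B"], n)
            obs = make_obs(t, lon, lat, loc_class=list(cls))
            params = CtcrwParams(beta=float(rng.uniform(0.1, 2)),
                                 sigma=float(rng.uniform(5, 50)))
            ll, _ = kalman_filter(obs, params, err)
            # oracle, coordinate by coordinate in the same projection
            from mtrack.ctcrw import _project_obs
            tt, z, r2, _ = _project_obs(obs, err, 1.0)
            ll0 = sum(
                dense_gaussian_loglik(tt, z[:, c], r2[:, c],
                                      params.beta_xy[c], params.sigma_xy[c])
                for c in (0, 1)
            )
            assert ll == pytest.approx(ll0, rel=1e-8, abs=1e-6)

    def test_inflated_observation_is_non_informative(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 20, 12)); t[0] = 0
        lon = 180 + np.cumsum(rng.normal(0, 0.05, 12))
        lat = -30 + np.cumsum(rng.normal(0, 0.05, 12))
        obs = make_obs(t, lon, lat)
        params = CtcrwParams(beta=0.8, sigma=20.0)
        err = ErrorModel()
        k = 6
        # inflate observation k's variance via a custom class table
        big = ErrorModel(k_mult={**err.k_mult, "B": (2e6, 2e6)})
        cls = ["3"] * 12
        cls[k] = "B"
        obs_big = make_obs(t, lon, lat, loc_class=cls)
        ll_inf, st_inf = kalman_filter(obs_big, params, big)
        obs_del = make_obs(np.delete(t, k), np.delete(lon, k), np.delete(lat, k))
        ll_del, st_del = kalman_filter(obs_del, params, err)
        # the inflated observation contributes only its own (flat) innovation
        from mtrack.ctcrw import _project_obs
        _, _, r2b, _ = _project_obs(obs_big, big, 1.0)
        own_term = sum(-0.5 * np.log(2 * np.pi * r2b[k, c]) for c in (0, 1))
        assert ll_inf - own_term == pytest.approx(ll_del, abs=1e-4)
        keep = [i for i in range(12) if i != k]
        np.testing.assert_allclose(
            st_inf.loc[keep, ["x_km", "y_km"]].to_numpy(),
            st_del[["x_km", "y_km"]].to_numpy(), atol=1e-4,
        )

    def test_error_scale_identifiability(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 20, 15)); t[0] = 0
        obs = make_obs(t, 180 + rng.normal(0, 0.3, 15), -30 + rng.normal(0, 0.3, 15))
        err1 = ErrorModel()
        err2 = ErrorModel(base_sd_lon_km=1.0, base_sd_lat_km=1.0,
                          gl_sd_lon_km=113.6, gl_sd_lat_km=224.4)
        ll1, _ = kalman_filter(obs, CtcrwParams(beta=1.0, sigma=10.0, error_scale=1.0), err1)
        ll2, _ = kalman_filter(obs, CtcrwParams(beta=1.0, sigma=10.0, error_scale=0.5), err2)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestFit:
    def test_optimum_beats_generating_params_and_is_init_independent(self):
        err = ErrorModel()
        obs = simulate_ctcrw_obs(0.8, 30.0, 150, 60.0, err.sd_km("1")[0], seed=5)
        fit1 = fit_ctcrw(obs, err, init=CtcrwParams(beta=0.3, sigma=10.0))
        fit2 = fit_ctcrw(obs, err, init=CtcrwParams(beta=2.0, sigma=80.0))
        ll_true, _ = kalman_filter(obs, CtcrwParams(beta=0.8, sigma=30.0), err)
        assert fit1.loglik >= ll_true - 1e-6
        assert fit1.params.beta_xy[0] == pytest.approx(fit2.params.beta_xy[0], rel=1e-4)
        assert fit1.params.sigma_xy[0] == pytest.approx(fit2.params.sigma_xy[0], rel=1e-4)
        assert fit1.converged


class TestSmoother:
    def test_near_exact_measurements_reproduced_at_observation_times(self, tiny_error_model):
        rng = np.random.default_rng(6)
        t = np.arange(0, 10.5, 0.5)
        lon = 180 + np.cumsum(rng.normal(0, 0.02, len(t)))
        lat = -30 + np.cumsum(rng.normal(0, 0.02, len(t)))
        obs = make_obs(t, lon, lat)
        params = CtcrwParams(beta=1.0, sigma=30.0)
        track = smooth_predict(obs, params, tiny_error_model, grid=t)
        d = np.hypot(track.df["x_km"] - track.df["x_km"],  # same grid as obs times
                     0.0)
        from mtrack.core_data import haversine_km
        dist = haversine_km((track.df["lon"].to_numpy(), track.df["lat"].to_numpy()),
                            (lon, lat))
        assert np.max(dist) < 1e-3

    def test_uncertainty_grows_inside_gaps(self):
        t = np.concatenate([np.arange(0, 5.1, 0.5), np.arange(15, 20.1, 0.5)])
        rng = np.random.default_rng(7)
        obs = make_obs(t, 180 + rng.normal(0, 0.1, len(t)),
                       -30 + rng.normal(0, 0.1, len(t)))
        err = ErrorModel()
        track = smooth_predict(obs, CtcrwParams(beta=0.8, sigma=20.0), err)
        df = track.df.set_index("t")
        assert df.loc[10.0, "sd_km"] > df.loc[4.5, "sd_km"]
        assert df.loc[10.0, "gap_days"] >= 4.5

    def test_gap_rows_flagged_low_confidence(self):
        t = np.concatenate([np.arange(0, 3.1, 0.5), np.arange(28, 31.1, 0.5)])
        rng = np.random.default_rng(8)
        obs = make_obs(t, 180 + rng.normal(0, 0.1, len(t)),
                       -30 + rng.normal(0, 0.1, len(t)))
        track = smooth_predict(obs, CtcrwParams(beta=0.8, sigma=20.0), ErrorModel(),
                               gap_flag_days=20.0)
        df = track.df.set_index("t")
        assert df.loc[15.0, "low_confidence"]
        assert not df.loc[1.0, "low_confidence"]

    def test_no_extrapolation_outside_span(self):
        rng = np.random.default_rng(9)
        t = np.arange(1.0, 9.1, 0.5)
        obs = make_obs(t, 180 + rng.normal(0, 0.1, len(t)),
                       -30 + rng.normal(0, 0.1, len(t)))
        with pytest.raises(ValueError, match="extrapolation"):
            smooth_predict(obs, CtcrwParams(), ErrorModel(), grid=np.arange(0.0, 12.0, 0.5))

    def test_grid_times_carry_no_information(self):
        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(0, 20, 30)); t[0] = 0; t[-1] = 20
        obs = make_obs(t, 180 + rng.normal(0, 0.2, 30), -30 + rng.normal(0, 0.2, 30))
        params = CtcrwParams(beta=0.8, sigma=20.0)
        err = ErrorModel()
        coarse = smooth_predict(obs, params, err, grid=np.arange(2.0, 19.0, 2.0))
        fine = smooth_predict(obs, params, err, grid=np.arange(2.0, 19.0, 1.0))
        merged = fine.df.set_index("t").loc[coarse.df["t"].to_numpy()]
        np.testing.assert_allclose(coarse.df["lon"].to_numpy(), merged["lon"], atol=1e-9)
        np.testing.assert_allclose(coarse.df["lat"].to_numpy(), merged["lat"], atol=1e-9)

    def test_smoother_is_a_projection(self, tiny_error_model):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 20, 40)); t[0] = 0; t[-1] = 20
        obs = make_obs(t, 180 + np.cumsum(rng.normal(0, 0.05, 40)),
                       -30 + np.cumsum(rng.normal(0, 0.05, 40)))
        params = CtcrwParams(beta=0.8, sigma=20.0)
        track = smooth_predict(obs, params, ErrorModel())
        pseudo = make_obs(track.df["t"], track.df["lon"], track.df["lat"])
        again = smooth_predict(pseudo, params, tiny_error_model, grid=track.df["t"].to_numpy())
        from mtrack.core_data import haversine_km
        dist = haversine_km(
            (track.df["lon"].to_numpy(), track.df["lat"].to_numpy()),
            (again.df["lon"].to_numpy(), again.df["lat"].to_numpy()),
        )
        assert np.max(dist) < 1e-2

    def test_regular_grid_anchored_at_half_days(self):
        g = regular_grid(0.3, 4.9)
        assert g[0] == 0.5 and g[-1] == 4.5
        assert np.allclose(np.diff(g), 0.5)


class TestRmsError:
    def test_identical_tracks_zero(self):
        df = pd.DataFrame({"lon": [180.0, 181.0], "lat": [-30.0, -31.0]})
        assert rms_error_km(df, df) == (0.0, 0.0)

    def test_constant_latitude_offset(self):
        a = pd.DataFrame({"lon": [180.0] * 5, "lat": np.linspace(-30, -29, 5)})
        b = a.copy()
        b["lat"] += 1.0 / (np.pi * 6371.0 / 180.0)  # exactly 1 km north
        r_lon, r_lat = rms_error_km(b, a)
        assert r_lon == pytest.approx(0.0, abs=1e-9)
        assert r_lat == pytest.approx(1.0, rel=1e-6)

    def test_gaussian_noise_recovers_sd(self):
        rng = np.random.default_rng(12)
        n = 10_000
        a = pd.DataFrame({"lon": np.full(n, 180.0), "lat": np.full(n, 0.0)})
        b = a.copy()
        b["lat"] += rng.normal(0, 10.0, n) / (np.pi * 6371.0 / 180.0)
        _, r_lat = rms_error_km(b, a)
        assert r_lat == pytest.approx(10.0, rel=0.02)

    def test_length_mismatch_rejected(self):
        a = pd.DataFrame({"lon": [180.0], "lat": [0.0]})
        b = pd.DataFrame({"lon": [180.0, 181.0], "lat": [0.0, 0.0]})
        with pytest.raises(ValueError):
            rms_error_km(a, b)
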