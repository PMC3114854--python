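"""Continuous-time correlated random walk (CTCRW) state-space model.

The movement model is an integrated Ornstein–Uhlenbeck velocity process: per
planar coordinate the state is (position, velocity) with

    v(t+dt) = e^{-beta dt} v(t) + zeta
    x(t+dt) = x(t) + v(t) (1 - e^{-beta dt}) / beta + xi

where (xi, zeta) are zero-mean Gaussian with the exact closed-form covariance
of the OU integral (see :func:`ctcrw_matrices`).  ``beta`` (1/day) controls
velocity autocorrelation, ``sigma`` the velocity diffusion scale.  Because
the transition is linear-Gaussian at any time lag, irregularly timed,
class-heteroscedastic observations are handled exactly by a Kalman filter,
and regular 12-h positions are obtained from the fixed-interval smoother.

Coordinates are projected per animal onto a local azimuthal-equidistant
tangent plane (km) before filtering and back-projected afterwards; the two
plane coordinates are filtered independently (shared or per-coordinate
parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core_data import (
    KM_PER_DEG,
    ErrorModel,
    LocalProjection,
    ObservationSet,
    normalize_lon,
)

logger = logging.getLogger(__name__)

#: diffuse prior variance on velocity (km^2/day^2)
V_DIFFUSE = 1.0e6


@dataclass(frozen=True)
class CtcrwParams:
    """CTCRW parameters.

    ``beta``/``sigma`` may be scalars (shared by east/north coordinates) or
    pairs ``(east, north)``.  ``error_scale`` is a free multiplier applied to
    every measurement SD from the :class:`~mtrack.core_data.ErrorModel`.
    """

    beta: float | tuple = 1.0      # velocity autocorrelation, 1/day
    sigma: float | tuple = 20.0    # velocity diffusion, km/day^(3/2)
    error_scale: float = 1.0

    def __post_init__(self):
        b, s = self.beta_xy, self.sigma_xy
        if not (np.all(np.isfinite(b)) and np.all(b > 0)):
            raise ValueError("beta must be positive and finite")
        if not (np.all(np.isfinite(s)) and np.all(s > 0)):
            raise ValueError("sigma must be positive and finite")
        if self.error_scale < 0:
            raise ValueError("error_scale must be >= 0")

    @property
    def beta_xy(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta, float), (2,)).copy()

    @property
    def sigma_xy(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.sigma, float), (2,)).copy()


@dataclass
class RegularTrack:
    """Smoothed positions at a fixed 12-h grid.

    ``df`` columns: animal_id, t (days), lon, lat (degrees), x_km, y_km
    (tangent-plane coordinates), sd_km (smoother position SD, combined
    east/north), gap_days (days to nearest observation), low_confidence.
    """

    df: pd.DataFrame
    step_days: float = 0.5
    projection: LocalProjection | None = None
    params: CtcrwParams | None = None

    def __len__(self):
        return len(self.df)


def ctcrw_matrices(params: CtcrwParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact (transition, process covariance) pair for one coordinate over a
    lag of ``dt`` days, using the first coordinate's (beta, sigma)."""
    T, Q = _ctcrw_mats(params.beta_xy[0], params.sigma_xy[0], dt)
    return T, Q


def _ctcrw_mats(beta: float, sigma: float, dt: float):
    if dt < 0:
        raise ValueError("dt must be >= 0")
    e = np.exp(-beta * dt)
    one_me = -np.expm1(-beta * dt)          # 1 - e^{-beta dt}
    one_me2 = -np.expm1(-2.0 * beta * dt)   # 1 - e^{-2 beta dt}
    T = np.array([[1.0, one_me / beta], [0.0, e]])
    s2 = sigma * sigma
    var_xi = s2 / beta**2 * (dt - 2.0 * one_me / beta + one_me2 / (2.0 * beta))
    var_zeta = s2 * one_me2 / (2.0 * beta)
    cov = s2 / (2.0 * beta**2) * one_me**2
    Q = np.array([[var_xi, cov], [cov, var_zeta]])
    # clip tiny negative round-off on the diagonal
    Q[0, 0] = max(Q[0, 0], 0.0)
    Q[1, 1] = max(Q[1, 1], 0.0)
    return T, Q


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _filter_coord(times, z, r2, beta, sigma):
    """Kalman filter for one coordinate.

    ``z`` may contain NaN (pseudo-times with no observation, used by the
    smoother); those steps are pure predictions.  ``r2`` is the measurement
    variance per time.  Returns (loglik, dict of stored moments).
    """
    n = len(times)
    H = np.array([1.0, 0.0])
    m_pred = np.zeros((n, 2))
    P_pred = np.zeros((n, 2, 2))
    m_filt = np.zeros((n, 2))
    P_filt = np.zeros((n, 2, 2))
    T_store = np.zeros((n, 2, 2))

    first_obs = int(np.flatnonzero(~np.isnan(z))[0])
    m = np.array([z[first_obs], 0.0])
    P = np.diag([r2[first_obs], V_DIFFUSE])
    loglik = 0.0
    for k in range(n):
        if k == 0:
            T = np.eye(2)
        else:
            T, Q = _ctcrw_mats(beta, sigma, times[k] - times[k - 1])
            m = T @ m
            P = T @ P @ T.T + Q
        T_store[k] = T
        m_pred[k], P_pred[k] = m, P
        if not np.isnan(z[k]):
            S = P[0, 0] + r2[k]
            if not np.isfinite(S) or S <= 0:
                raise RuntimeError(f"singular innovation covariance at timestep {k} (t={times[k]})")
            v = z[k] - m[0]
            K = P @ H / S
            m = m + K * v
            P = P - np.outer(K, H @ P)
            P = 0.5 * (P + P.T)
            loglik += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
        m_filt[k], P_filt[k] = m, P
    return loglik, dict(m_pred=m_pred, P_pred=P_pred, m_filt=m_filt, P_filt=P_filt, T=T_store)


def _project_obs(obs: ObservationSet, err: ErrorModel, error_scale: float):
    df = obs.df
    if df["animal_id"].nunique() != 1:
        raise ValueError("filter operates on a single animal's observations")
    if len(df) < 2:
        raise ValueError("need at least 2 observations")
    t = df["t"].to_numpy(float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(df[["lon", "lat"]].to_numpy())):
        raise ValueError("non-finite observation values")
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    # centre on the track midpoint; longitudes are stored in [0,360) so a
    # plain mean is monotone-safe for antimeridian-spanning tracks
    proj = LocalProjection(0.5 * (lon.min() + lon.max()), 0.5 * (lat.min() + lat.max()))
    x, y = proj.forward(lon, lat)
    sd_lon, sd_lat = err.sd_km_arrays(df["loc_class"])
    r2 = np.column_stack([(sd_lon * error_scale) ** 2, (sd_lat * error_scale) ** 2])
    z = np.column_stack([x, y])
    return t, z, r2, proj


def kalman_filter(obs: ObservationSet, params: CtcrwParams, err: ErrorModel):
    """Prediction-error-decomposition log-likelihood and filtered states.

    Returns ``(loglik, filtered)`` where ``filtered`` is a DataFrame with the
    filtered position/velocity mean and position SD per coordinate at each
    observation time.
    """
    t, z, r2, proj = _project_obs(obs, err, params.error_scale)
    beta, sigma = params.beta_xy, params.sigma_xy
    loglik = 0.0
    cols = {}
    for c, name in ((0, "x"), (1, "y")):
        ll, st = _filter_coord(t, z[:, c], r2[:, c], beta[c], sigma[c])
        loglik += ll
        cols[f"{name}_km"] = st["m_filt"][:, 0]
        cols[f"v{name}_kmday"] = st["m_filt"][:, 1]
        cols[f"sd_{name}_km"] = np.sqrt(st["P_filt"][:, 0, 0])
    filtered = pd.DataFrame({"t": t, **cols})
    return loglik, filtered


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class CtcrwFit:
    params: CtcrwParams
    loglik: float
    converged: bool
    n_obs: int
    log_param_cov: np.ndarray | None = None
    message: str = ""


def fit_ctcrw(
    obs: ObservationSet,
    err: ErrorModel,
    init: CtcrwParams | None = None,
    bounds: tuple = ((1e-3, 1e3), (1e-2, 1e4)),
    shared: bool = True,
) -> CtcrwFit:
    """Maximize the filter likelihood over log(beta), log(sigma).

    A single (beta, sigma) pair shared by both plane coordinates is fitted by
    default; ``error_scale`` is carried through from ``init`` unchanged.
    Deterministic given data and init (bounded quasi-Newton on the log scale).
    """
    init = init or CtcrwParams()
    if len(obs.df) < 20:
        logger.warning("fit_ctcrw with <20 observations; estimates may be unstable")
    t, z, r2, _ = _project_obs(obs, err, init.error_scale)

    if shared:
        def nll(logp):
            b, s = np.exp(logp)
            try:
                return -sum(
                    _filter_coord(t, z[:, c], r2[:, c], b, s)[0] for c in (0, 1)
                )
            except (RuntimeError, FloatingPointError):
                return 1e12

        x0 = np.log([init.beta_xy[0], init.sigma_xy[0]])
        log_bounds = [tuple(np.log(b)) for b in bounds]
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=log_bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        beta_hat, sigma_hat = np.exp(res.x)
        fitted = CtcrwParams(beta=float(beta_hat), sigma=float(sigma_hat),
                             error_scale=init.error_scale)
        cov = _numeric_log_cov(nll, res.x)
    else:
        # independent 1-D problems per coordinate
        betas, sigmas, res_ok, fun = [], [], True, 0.0
        for c in (0, 1):
            def nll_c(logp, c=c):
                b, s = np.exp(logp)
                try:
                    return -_filter_coord(t, z[:, c], r2[:, c], b, s)[0]
                except (RuntimeError, FloatingPointError):
                    return 1e12
            x0 = np.log([init.beta_xy[c], init.sigma_xy[c]])
            r = optimize.minimize(nll_c, x0, method="L-BFGS-B",
                                  bounds=[tuple(np.log(b)) for b in bounds],
                                  options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
            betas.append(float(np.exp(r.x[0])))
            sigmas.append(float(np.exp(r.x[1])))
            res_ok &= bool(r.success)
            fun += r.fun
        fitted = CtcrwParams(beta=tuple(betas), sigma=tuple(sigmas),
                             error_scale=init.error_scale)
        return CtcrwFit(fitted, -fun, res_ok, len(t), None, "per-coordinate fit")

    fit = CtcrwFit(fitted, -float(res.fun), bool(res.success), len(t), cov,
                   str(res.message))
    if not res.success:
        logger.warning("fit_ctcrw did not converge: %s", res.message)
    return fit


def _numeric_log_cov(nll, x, h=1e-4):
    """Finite-difference Hessian of the negative log-likelihood → covariance
    of the log-parameters; None if the Hessian is not positive definite."""
    n = len(x)
    H = np.zeros((n, n))
    f0 = nll(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                nll(x + ei + ej) - nll(x + ei) - nll(x + ej) + f0
            ) / (h * h)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            return None
        return cov
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# smoothing / 12-h prediction
# ---------------------------------------------------------------------------

def _smooth_coord(times, z, r2, beta, sigma):
    """RTS fixed-interval smoother for one coordinate over (possibly
    pseudo-) times.  Returns smoothed means and covariances."""
    _, st = _filter_coord(times, z, r2, beta, sigma)
    n = len(times)
    m_s = st["m_filt"].copy()
    P_s = st["P_filt"].copy()
    for k in range(n - 2, -1, -1):
        T = st["T"][k + 1]
        P_pred = st["P_pred"][k + 1]
        # Joseph-free gain with a ridge for numerically singular predictions
        G = st["P_filt"][k] @ T.T @ np.linalg.inv(P_pred + 1e-12 * np.eye(2))
        m_s[k] = st["m_filt"][k] + G @ (m_s[k + 1] - st["m_pred"][k + 1])
        P_s[k] = st["P_filt"][k] + G @ (P_s[k + 1] - P_pred) @ G.T
        P_s[k] = 0.5 * (P_s[k] + P_s[k].T)
    return m_s, P_s


def regular_grid(t_first: float, t_last: float, step_days: float = 0.5) -> np.ndarray:
    """12-h grid times (multiples of ``step_days`` since release) inside the
    observation span."""
    k0 = int(np.ceil(round(t_first / step_days, 9)))
    k1 = int(np.floor(round(t_last / step_days, 9)))
    return np.arange(k0, k1 + 1) * step_days


def smooth_predict(
    obs: ObservationSet,
    fitted: CtcrwParams,
    err: ErrorModel,
    grid: np.ndarray | None = None,
    step_days: float = 0.5,
    gap_flag_days: float = 20.0,
) -> RegularTrack:
    """Fixed-interval smoother evaluated on a regular grid.

    The smoother runs on the union of observation and grid times (grid times
    carry no observation, hence no information) and the grid rows are
    returned, back-projected to lon/lat.  Grid rows falling in an
    observation gap longer than ``gap_flag_days`` are flagged low-confidence
    rather than dropped.
    """
    t_obs, z, r2, proj = _project_obs(obs, err, fitted.error_scale)
    animal_id = obs.df["animal_id"].iloc[0]
    if grid is None:
        grid = regular_grid(t_obs[0], t_obs[-1], step_days)
    grid = np.asarray(grid, float)
    if len(grid) and (grid[0] < t_obs[0] - 1e-9 or grid[-1] > t_obs[-1] + 1e-9):
        raise ValueError("grid extends outside the observation span (no extrapolation)")

    t_all = np.concatenate([t_obs, grid])
    z_all = np.vstack([z, np.full((len(grid), 2), np.nan)])
    r2_all = np.vstack([r2, np.ones((len(grid), 2))])
    order = np.argsort(t_all, kind="mergesort")
    t_all, z_all, r2_all = t_all[order], z_all[order], r2_all[order]
    # collapse exactly duplicated times (grid time == obs time): keep the obs
    keep = np.ones(len(t_all), bool)
    is_grid_row = np.isnan(z_all[:, 0])
    for i in range(1, len(t_all)):
        if t_all[i] - t_all[i - 1] < 1e-12 and is_grid_row[i]:
            keep[i] = False
        elif t_all[i] - t_all[i - 1] < 1e-12 and is_grid_row[i - 1]:
            keep[i - 1] = False
    t_all, z_all, r2_all = t_all[keep], z_all[keep], r2_all[keep]

    beta, sigma = fitted.beta_xy, fitted.sigma_xy
    means = np.zeros((len(t_all), 2))
    variances = np.zeros((len(t_all), 2))
    for c in (0, 1):
        m_s, P_s = _smooth_coord(t_all, z_all[:, c], r2_all[:, c], beta[c], sigma[c])
        means[:, c] = m_s[:, 0]
        variances[:, c] = np.maximum(P_s[:, 0, 0], 0.0)

    # pick the grid rows (nearest stored time for each requested grid time)
    idx = np.searchsorted(t_all, grid - 1e-12)
    idx = np.clip(idx, 0, len(t_all) - 1)
    x_g, y_g = means[idx, 0], means[idx, 1]
    sd_g = np.sqrt(variances[idx, 0] + variances[idx, 1])
    lon_g, lat_g = proj.inverse(x_g, y_g)

    # gap metadata against the *observation* times
    j = np.searchsorted(t_obs, grid)
    j_prev = np.clip(j - 1, 0, len(t_obs) - 1)
    j_next = np.clip(j, 0, len(t_obs) - 1)
    gap_days = np.minimum(np.abs(grid - t_obs[j_prev]), np.abs(t_obs[j_next] - grid))
    spanning_gap = t_obs[j_next] - t_obs[j_prev]
    low_conf = spanning_gap > gap_flag_days

    df = pd.DataFrame({
        "animal_id": animal_id,
        "t": grid,
        "lon": lon_g,
        "lat": lat_g,
        "x_km": x_g,
        "y_km": y_g,
        "sd_km": sd_g,
        "gap_days": gap_days,
        "low_confidence": low_conf,
    })
    return RegularTrack(df=df, step_days=step_days, projection=proj, params=fitted)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def rms_error_km(estimate: pd.DataFrame, truth: pd.DataFrame) -> tuple[float, float]:
    """Coordinatewise RMS error (lon km, lat km) between two tracks sharing a
    time grid.  Longitude displacement is measured along the local parallel.
    """
    if len(estimate) != len(truth):
        raise ValueError("tracks must share a common time grid (length mismatch)")
    lon_e = normalize_lon(estimate["lon"].to_numpy(float))
    lon_t = normalize_lon(truth["lon"].to_numpy(float))
    lat_e = estimate["lat"].to_numpy(float)
    lat_t = truth["lat"].to_numpy(float)
    dlon = (lon_e - lon_t + 180.0) % 360.0 - 180.0
    dlon_km = dlon * KM_PER_DEG * np.cos(np.radians(0.5 * (lat_e + lat_t)))
    dlat_km = (lat_e - lat_t) * KM_PER_DEG
    return float(np.sqrt(np.mean(dlon_km**2))), float(np.sqrt(np.mean(dlat_km**2)))
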