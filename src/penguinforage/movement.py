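"""Continuous-time correlated random walk (CTCRW) movement modelling.

The horizontal movement model treats velocity as an Ornstein–Uhlenbeck
process (mean-reverting to zero at rate ``beta``, driven at scale
``sigma``) and position as its integral. Irregular GPS fixes with
Gaussian measurement error are filtered with a Kalman filter per planar
axis; maximum-likelihood estimates of (beta, sigma, meas_err_sd) come
from numerically optimising the exact filter likelihood. Latent positions
at arbitrary times (dive times) are imputed by forward-filter
backward-sampling so that each imputation is a coherent trajectory.

Dive-density surfaces are built on a fixed lon/lat grid: each imputation
draw contributes equal weight, and the per-cell density per day is

    cell_proportion × (pairs × 2) × (P × 24) × dive_rate

where P is the proportion of time at sea and dive_rate is per hour, so
the sum over cells equals the colony's total dives per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EARTH_M_PER_DEG_LAT",
    "to_planar",
    "to_lonlat",
    "iou_transition",
    "simulate_ctcrw_track",
    "CTCRWFit",
    "ctcrw_loglik",
    "fit_ctcrw",
    "impute_dive_locations",
    "GridDensityMap",
    "grid_dive_density",
    "density_difference",
    "DistanceRegression",
    "fit_distance_regression",
    "path_length",
    "max_displacement",
]

EARTH_M_PER_DEG_LAT = 111_320.0


def to_planar(lon, lat, origin):
    """Project lon/lat (deg) to a local tangent plane (metres) at ``origin``.

    Equirectangular approximation centred on the colony; adequate at the
    tens-of-kilometres scale of inshore foraging trips.
    """
    lon0, lat0 = origin
    x = (np.asarray(lon) - lon0) * EARTH_M_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    y = (np.asarray(lat) - lat0) * EARTH_M_PER_DEG_LAT
    return x, y


def to_lonlat(x, y, origin):
    """Inverse of :func:`to_planar`."""
    lon0, lat0 = origin
    lon = lon0 + np.asarray(x) / (EARTH_M_PER_DEG_LAT * np.cos(np.deg2rad(lat0)))
    lat = lat0 + np.asarray(y) / EARTH_M_PER_DEG_LAT
    return lon, lat


def iou_transition(beta: float, sigma: float, dt: float):
    """State transition (F) and innovation covariance (Q) of the
    integrated OU process over a step ``dt`` for state (position, velocity)."""
    e = np.exp(-beta * dt)
    F = np.array([[1.0, (1.0 - e) / beta], [0.0, e]])
    s2 = sigma * sigma
    qv = s2 * (1.0 - e * e) / (2.0 * beta)
    qxv = s2 * (1.0 - 2.0 * e + e * e) / (2.0 * beta * beta)
    qx = (s2 / (beta * beta)) * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta))
    Q = np.array([[qx, qxv], [qxv, qv]])
    return F, Q


def simulate_ctcrw_track(
    times,
    beta: float,
    sigma: float,
    meas_err_sd: float,
    rng: np.random.Generator,
    start_xy=(0.0, 0.0),
    bridge: bool = False,
):
    """Simulate a CTCRW track observed at ``times`` (seconds).

    Velocity starts from its stationary distribution. With ``bridge=True``
    the path is conditioned (by Gaussian conditioning on the free path's
    endpoint) to end at the start point, emulating a central-place
    foraging trip that departs from and returns to the colony.

    Returns a DataFrame with columns time_s, x, y (true) and x_obs, y_obs
    (with measurement error).
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    if n < 2:
        raise ValueError("need at least two time points")
    xy_true = np.zeros((n, 2))
    for axis in range(2):
        state = np.array([0.0, rng.normal(0.0, sigma / np.sqrt(2.0 * beta)) if sigma > 0 else 0.0])
        path = np.zeros(n)
        path[0] = state[0]
        for k in range(1, n):
            F, Q = iou_transition(beta, sigma, times[k] - times[k - 1])
            mean = F @ state
            if sigma > 0:
                state = rng.multivariate_normal(mean, Q)
            else:
                state = mean
            path[k] = state[0]
        if bridge and path[-1] != 0.0:
            # Linear-in-time removal of the endpoint: the integrated-OU
            # bridge correction is approximated by detrending, which pins
            # both ends exactly while preserving local roughness.
            path = path - (times - times[0]) / (times[-1] - times[0]) * path[-1]
        xy_true[:, axis] = path
    xy_true += np.asarray(start_xy)
    obs = xy_true + rng.normal(0.0, meas_err_sd, size=xy_true.shape)
    return pd.DataFrame(
        {
            "time_s": times,
            "x": xy_true[:, 0],
            "y": xy_true[:, 1],
            "x_obs": obs[:, 0],
            "y_obs": obs[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Kalman filtering and fitting
# ---------------------------------------------------------------------------

_INIT_POS_SD = 1.0e4  # prior SD (m) on the initial position, centred on the first fix


def _filter_axis(times, obs, beta, sigma, tau, collect=False):
    """Kalman filter of one planar axis.

    ``obs`` may contain NaN for unobserved (imputation) times. Returns the
    log-likelihood and, when ``collect``, the filtered means/covariances
    and one-step predictions needed by the backward sampler.
    """
    n = times.size
    first = int(np.flatnonzero(~np.isnan(obs))[0])
    m = np.array([obs[first], 0.0])
    P = np.diag([_INIT_POS_SD**2, sigma * sigma / (2.0 * beta) if sigma > 0 else 1e-12])
    ll = 0.0
    trans_cache: dict = {}  # dt repeats under regular sampling

    def transition(dt):
        hit = trans_cache.get(dt)
        if hit is None:
            hit = iou_transition(beta, sigma, dt)
            trans_cache[dt] = hit
        return hit
    if collect:
        ms = np.zeros((n, 2))
        Ps = np.zeros((n, 2, 2))
        m_pred = np.zeros((n, 2))
        P_pred = np.zeros((n, 2, 2))
    for k in range(n):
        if k > 0:
            F, Q = transition(times[k] - times[k - 1])
            m = F @ m
            P = F @ P @ F.T + Q
        if collect:
            m_pred[k] = m
            P_pred[k] = P
        yk = obs[k]
        if not np.isnan(yk):
            S = P[0, 0] + tau * tau
            v = yk - m[0]
            ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
            K = P[:, 0] / S
            m = m + K * v
            P = P - np.outer(K, P[0, :])
        if collect:
            ms[k] = m
            Ps[k] = P
    if collect:
        return ll, ms, Ps, m_pred, P_pred
    return ll


def ctcrw_loglik(segments, beta, sigma, tau):
    """Exact CTCRW log-likelihood summed over track segments and axes.

    ``segments`` is a list of (times, x_obs, y_obs) arrays.
    """
    ll = 0.0
    for times, x, y in segments:
        ll += _filter_axis(times, x, beta, sigma, tau)
        ll += _filter_axis(times, y, beta, sigma, tau)
    return ll


@dataclass
class CTCRWFit:
    """Fitted CTCRW movement model.

    beta is the velocity-autocorrelation decay (s⁻¹); sigma the velocity
    stochasticity scale (m s⁻¹·s⁻¹ᐟ²); meas_err_sd the GPS error SD (m).
    """

    beta: float
    sigma: float
    meas_err_sd: float
    log_likelihood: float
    segments: list = field(repr=False)
    origin: tuple | None = None
    converged: bool = True

    def segment_spans(self):
        return [(seg[0][0], seg[0][-1]) for seg in self.segments]


def _as_segments(fixes: pd.DataFrame):
    cols = {"time_s", "x", "y"}
    if not cols.issubset(fixes.columns):
        raise ValueError(f"fixes must have columns {sorted(cols)}")
    if "trip" in fixes.columns:
        groups = [g for _, g in fixes.groupby("trip", sort=True)]
    else:
        groups = [fixes]
    segments = []
    for g in groups:
        t = g["time_s"].to_numpy(dtype=float)
        if t.size < 4:
            raise ValueError("each trip needs at least 4 fixes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("fix times must be strictly increasing within a trip")
        segments.append((t, g["x"].to_numpy(dtype=float), g["y"].to_numpy(dtype=float)))
    return segments


def fit_ctcrw(
    fixes: pd.DataFrame,
    init=None,
    estimate_meas_err: bool = True,
    meas_err_sd: float = 25.0,
    origin=None,
    n_starts: int = 3,
) -> CTCRWFit:
    """Maximum-likelihood CTCRW fit to irregular planar fixes.

    ``fixes`` needs columns time_s, x, y (metres) and optionally trip.
    Optimisation runs on log-parameters with multiple starts. When
    ``estimate_meas_err`` is False the measurement SD is held at
    ``meas_err_sd``.
    """
    segments = _as_segments(fixes)
    spread = max(
        float(np.ptp(np.concatenate([s[1] for s in segments]))),
        float(np.ptp(np.concatenate([s[2] for s in segments]))),
    )
    if init is None:
        init = {}
    beta0 = init.get("beta", 1.0 / 600.0)
    sigma0 = init.get("sigma", 0.05 if spread > 0 else 1e-4)
    tau0 = init.get("meas_err_sd", meas_err_sd)

    def nll(theta):
        beta = np.exp(theta[0])
        sigma = np.exp(theta[1])
        tau = np.exp(theta[2]) if estimate_meas_err else meas_err_sd
        if not np.isfinite(beta) or beta <= 0:
            return 1e12
        return -ctcrw_loglik(segments, beta, sigma, tau)

    x0 = np.log([beta0, sigma0, max(tau0, 1e-3)])
    if not estimate_meas_err:
        x0 = x0[:3]
    best = None
    offsets = [np.zeros(3), np.array([1.0, 1.0, 0.0]), np.array([-1.0, -1.0, 0.0])]
    for start in offsets[:n_starts]:
        res = optimize.minimize(
            nll, x0 + start, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("CTCRW optimisation failed to produce a finite likelihood")
    beta = float(np.exp(best.x[0]))
    sigma = float(np.exp(best.x[1]))
    tau = float(np.exp(best.x[2])) if estimate_meas_err else float(meas_err_sd)
    if sigma < 1e-6 * max(spread, 1.0):
        warnings.warn("sigma estimate is at/near zero (degenerate geometry)", stacklevel=2)
    return CTCRWFit(
        beta=beta,
        sigma=sigma,
        meas_err_sd=tau,
        log_likelihood=float(-best.fun),
        segments=segments,
        origin=origin,
        converged=bool(best.success),
    )


def _ffbs_axis(times, obs, beta, sigma, tau, n_draws, rng):
    """Forward-filter backward-sample n_draws joint state paths (one axis)."""
    _, ms, Ps, m_pred, P_pred = _filter_axis(times, obs, beta, sigma, tau, collect=True)
    n = times.size
    draws = np.zeros((n_draws, n, 2))
    cov = 0.5 * (Ps[-1] + Ps[-1].T) + 1e-12 * np.eye(2)
    draws[:, -1, :] = rng.multivariate_normal(ms[-1], cov, size=n_draws)
    for k in range(n - 2, -1, -1):
        F, _ = iou_transition(beta, sigma, times[k + 1] - times[k])
        Pp = P_pred[k + 1]
        G = Ps[k] @ F.T @ np.linalg.inv(Pp + 1e-12 * np.eye(2))
        cond_cov = Ps[k] - G @ Pp @ G.T
        cond_cov = 0.5 * (cond_cov + cond_cov.T) + 1e-12 * np.eye(2)
        L = np.linalg.cholesky(cond_cov)
        resid = draws[:, k + 1, :] - m_pred[k + 1]
        mean = ms[k] + resid @ G.T
        z = rng.standard_normal((n_draws, 2))
        draws[:, k, :] = mean + z @ L.T
    return draws


def impute_dive_locations(
    fit: CTCRWFit, dive_times, n: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` joint trajectory positions at each dive time.

    Each imputation is one backward-sampled latent path evaluated at the
    dive times, so neighbouring dives within an imputation respect path
    continuity. Dive times outside every fitted segment's span are flagged
    as extrapolations and assigned to the nearest segment.

    Returns a tidy DataFrame: dive_id, imputation, x, y (and lon/lat when
    the fit carries an origin), extrapolated.
    """
    dive_times = np.asarray(dive_times, dtype=float)
    if n < 1:
        raise ValueError("n_imputations must be >= 1")
    if dive_times.size == 0:
        return pd.DataFrame(columns=["dive_id", "imputation", "x", "y", "extrapolated"])
    rng = np.random.default_rng(seed)
    spans = fit.segment_spans()

    def locate(t):
        for si, (a, b) in enumerate(spans):
            if a <= t <= b:
                return si, False
        si = int(np.argmin([min(abs(t - a), abs(t - b)) for a, b in spans]))
        return si, True

    seg_of = np.zeros(dive_times.size, dtype=int)
    extrap = np.zeros(dive_times.size, dtype=bool)
    for i, t in enumerate(dive_times):
        seg_of[i], extrap[i] = locate(t)
    records = []
    for si, (times, x, y) in enumerate(fit.segments):
        idx = np.flatnonzero(seg_of == si)
        if idx.size == 0:
            continue
        t_aug = np.concatenate([times, dive_times[idx]])
        obs_x = np.concatenate([x, np.full(idx.size, np.nan)])
        obs_y = np.concatenate([y, np.full(idx.size, np.nan)])
        order = np.argsort(t_aug, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        dx = _ffbs_axis(t_aug[order], obs_x[order], fit.beta, fit.sigma, fit.meas_err_sd, n, rng)
        dy = _ffbs_axis(t_aug[order], obs_y[order], fit.beta, fit.sigma, fit.meas_err_sd, n, rng)
        for j, di in enumerate(idx):
            pos = inv[times.size + j]
            for m in range(n):
                records.append((int(di), m, dx[m, pos, 0], dy[m, pos, 0], bool(extrap[di])))
    out = pd.DataFrame(records, columns=["dive_id", "imputation", "x", "y", "extrapolated"])
    out = out.sort_values(["dive_id", "imputation"], ignore_index=True)
    if fit.origin is not None:
        lon, lat = to_lonlat(out["x"].to_numpy(), out["y"].to_numpy(), fit.origin)
        out["lon"] = lon
        out["lat"] = lat
    return out


# ---------------------------------------------------------------------------
# Gridded dive density
# ---------------------------------------------------------------------------


@dataclass
class GridDensityMap:
    """Dives-per-day surface on a regular lon/lat grid.

    Cells are half-open [origin + i·cell, origin + (i+1)·cell) in both
    axes, indexed (i, j) = (lon index, lat index).
    """

    cell_size: float
    origin: tuple
    cells: dict
    stage: str = ""

    def total(self) -> float:
        return float(sum(self.cells.values()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (i, j, self.origin[0] + i * self.cell_size, self.origin[1] + j * self.cell_size, d)
            for (i, j), d in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["i", "j", "lon_min", "lat_min", "dives_per_day"])


def grid_dive_density(
    draws: pd.DataFrame,
    prop_at_sea: float,
    dive_rate_per_h: float,
    pairs: int,
    cell_size: float = 0.005,
    origin=(-38.05, -54.01),
    stage: str = "",
) -> GridDensityMap:
    """Grid imputation draws into a dives-per-day density surface.

    ``draws`` needs lon and lat columns (one row per imputation draw; all
    draws carry equal weight, so each dive's 1/n_imputations weighting is
    automatic). The per-cell density is the product of the
    cell's proportion of dives, birds (pairs × 2), hours at sea per day
    (P × 24), and dive rate per hour.
    """
    if len(draws) == 0:
        raise ValueError("no imputation draws to grid")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    lon = draws["lon"].to_numpy(dtype=float)
    lat = draws["lat"].to_numpy(dtype=float)
    i = np.floor((lon - origin[0]) / cell_size).astype(int)
    j = np.floor((lat - origin[1]) / cell_size).astype(int)
    total_per_day = (pairs * 2) * (prop_at_sea * 24.0) * dive_rate_per_h
    cells: dict = {}
    keys, counts = np.unique(np.stack([i, j], axis=1), axis=0, return_counts=True)
    for (ci, cj), c in zip(keys, counts):
        cells[(int(ci), int(cj))] = (c / lon.size) * total_per_day
    return GridDensityMap(cell_size=cell_size, origin=tuple(origin), cells=cells, stage=stage)


def density_difference(map_a: GridDensityMap, map_b: GridDensityMap) -> GridDensityMap:
    """Cellwise ``map_b − map_a`` over the union of cells (absent cells = 0)."""
    if map_a.cell_size != map_b.cell_size or map_a.origin != map_b.origin:
        raise ValueError("grids are not registered identically")
    keys = set(map_a.cells) | set(map_b.cells)
    cells = {k: map_b.cells.get(k, 0.0) - map_a.cells.get(k, 0.0) for k in keys}
    return GridDensityMap(
        cell_size=map_a.cell_size,
        origin=map_a.origin,
        cells=cells,
        stage=f"{map_b.stage}-{map_a.stage}",
    )


# ---------------------------------------------------------------------------
# Duration → distance regressions
# ---------------------------------------------------------------------------


@dataclass
class DistanceRegression:
    """OLS of √distance (km) on trip duration (minutes)."""

    intercept: float
    slope: float
    response: str
    se_intercept: float = np.nan
    se_slope: float = np.nan
    fvalue: float = np.nan
    p_value: float = np.nan

    def predict(self, duration_min):
        root = self.intercept + self.slope * np.asarray(duration_min, dtype=float)
        return root**2


def fit_distance_regression(
    durations_min, distances_km, response: str = "total_distance"
) -> DistanceRegression:
    """Fit √distance = a + b·t by ordinary least squares."""
    import statsmodels.api as sm

    t = np.asarray(durations_min, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 trips")
    if np.ptp(t) == 0:
        raise ValueError("degenerate input: all durations identical")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    X = sm.add_constant(t)
    fit = sm.OLS(np.sqrt(d), X).fit()
    return DistanceRegression(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        response=response,
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        fvalue=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
    )


def path_length(x, y) -> float:
    """Total along-path distance (same units as x/y)."""
    return float(np.sum(np.hypot(np.diff(np.asarray(x)), np.diff(np.asarray(y)))))


def max_displacement(x, y, origin_xy=(0.0, 0.0)) -> float:
    """Maximum distance from ``origin_xy`` along a track."""
    return float(np.max(np.hypot(np.asarray(x) - origin_xy[0], np.asarray(y) - origin_xy[1])))
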