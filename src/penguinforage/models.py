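"""Stage-comparison inferential models.

Linear mixed models in the nlme tradition: Gaussian responses with
optional transforms, random intercepts for individual or trip nested in
individual, a first-order autoregressive (AR(1)) residual correlation
within trips, and residual variances stratified by breeding stage. Fits
are maximum likelihood (not REML) so likelihood-ratio tests of fixed
effects are valid; model selection is backward stepwise deletion with
LR tests.

The marginal likelihood treats each individual's observations as one
structured multivariate normal. Rather than forming dense covariance
matrices it whitens within trips against the AR(1) correlation (O(n))
and handles the random intercepts with the Woodbury identity on a small
(1 + trips-per-individual) system; the global residual scale is profiled
out analytically, leaving a low-dimensional numeric optimisation over
relative variance components, stage variance ratios and the AR(1)
coefficient.

Also here: the Poisson dive-rate model with a log-exposure offset, a
variance-components accounting of how much individual-level variance a
covariate explains, and closed-form ML generalized-least-squares
comparisons of two groups in mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "LRTest",
    "fit_mixed_model",
    "lr_test",
    "backward_select",
    "PoissonRateFit",
    "fit_poisson_rate",
    "variance_components_explained",
    "GroupComparison",
    "compare_groups_gls",
]

_TRANSFORMS = {
    "identity": (lambda y: y, lambda z: z),
    "sqrt": (np.sqrt, lambda z: z**2),
    "arcsine": (lambda y: np.arcsin(np.sqrt(y)), lambda z: np.sin(z) ** 2),
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response/transform, fixed terms, covariance structure."""

    response: str
    transform: str = "identity"
    fixed: tuple = ()
    random: str = "none"  # none | individual | trip_in_individual
    ar1_within_trip: bool = False
    variance_by_stage: bool = False
    individual_col: str = "bird_id"
    trip_col: str = "trip_id"
    stage_col: str = "stage"

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.random not in ("none", "individual", "trip_in_individual"):
            raise ValueError(f"unsupported random structure {self.random!r}")


@dataclass
class LRTest:
    statistic: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    """ML fit: fixed effects ± SE, variance components, AR(1), strata."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    vc: dict  # individual/trip variance components (natural-scale variances)
    residual_sd: dict  # stratum -> residual SD (single key "" if unstratified)
    ar1_phi: float
    log_likelihood: float
    n_obs: int
    n_params: int
    term_columns: dict = field(repr=False, default_factory=dict)
    cov_params: np.ndarray = field(repr=False, default=None)

    @property
    def variance_ratio(self) -> float:
        """Residual variance ratio between strata (second / first); 1 if unstratified."""
        sds = [self.residual_sd[k] for k in self.residual_sd]
        if len(sds) < 2:
            return 1.0
        return (sds[1] / sds[0]) ** 2

    def transformed_mean(self, **covariates) -> float:
        """Linear predictor on the transformed scale for given covariates."""
        x = _row_for(self.params.index, self.term_columns, covariates)
        return float(x @ self.params.to_numpy())

    def natural_mean(self, **covariates) -> float:
        """Back-transformed fitted mean (inverse transform of the linear
        predictor; a median, not a mean, under nonlinear transforms)."""
        inv = _TRANSFORMS[self.spec.transform][1]
        return float(inv(self.transformed_mean(**covariates)))


def _design(data: pd.DataFrame, fixed) -> tuple[np.ndarray, list, dict]:
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    term_cols = {"(Intercept)": ["(Intercept)"]}
    for term in fixed:
        s = data[term]
        if s.dtype.kind in "biufc" and s.dtype.kind != "b":
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
            term_cols[term] = [term]
        else:
            levels = sorted(pd.unique(s.astype(str)))
            term_cols[term] = []
            for lvl in levels[1:]:
                cols.append((s.astype(str) == lvl).to_numpy(dtype=float))
                name = f"{term}[{lvl}]"
                names.append(name)
                term_cols[term].append(name)
            if not term_cols[term]:
                raise ValueError(f"fixed term {term!r} has a single level")
    return np.column_stack(cols), names, term_cols


def _row_for(names, term_cols, covariates) -> np.ndarray:
    x = np.zeros(len(names))
    for i, nm in enumerate(names):
        if nm == "(Intercept)":
            x[i] = 1.0
        elif "[" in nm:
            term, lvl = nm.split("[", 1)
            lvl = lvl[:-1]
            x[i] = 1.0 if str(covariates.get(term)) == lvl else 0.0
        else:
            x[i] = float(covariates.get(nm, 0.0))
    return x


def _blocks(data, spec):
    """Row-index blocks (by individual, else trip, else all) with trip splits."""
    idx = np.arange(len(data))
    if spec.random != "none" and spec.individual_col in data.columns:
        groups = data.groupby(spec.individual_col, sort=True).indices
        blocks = [np.asarray(v) for _, v in sorted(groups.items())]
    elif spec.ar1_within_trip:
        groups = data.groupby(spec.trip_col, sort=True).indices
        blocks = [np.asarray(v) for _, v in sorted(groups.items())]
    else:
        blocks = [idx]
    out = []
    for b in blocks:
        if spec.ar1_within_trip or spec.random == "trip_in_individual":
            trips = data.iloc[b].groupby(spec.trip_col, sort=True).indices
            trip_slices = [b[np.asarray(v)] for _, v in sorted(trips.items())]
        else:
            trip_slices = [b]
        out.append(trip_slices)
    return out


def _profiled_nll(theta, layout):
    """Profiled negative log-likelihood; returns (−ℓ, extras)."""
    (blocks, X, y, strat_id, n_strata, has_ind, has_trip, ar1) = layout
    pos = 0
    g_ind = np.exp(theta[pos]) if has_ind else 0.0
    pos += int(has_ind)
    g_trip = np.exp(theta[pos]) if has_trip else 0.0
    pos += int(has_trip)
    rel_sd = np.ones(n_strata)
    for m in range(1, n_strata):
        rel_sd[m] = np.exp(theta[pos])
        pos += 1
    phi = np.tanh(theta[pos]) if ar1 else 0.0

    p = X.shape[1]
    n = y.size
    M = np.zeros((p + 1, p + 1))
    logdetV = 0.0
    U = np.column_stack([X, y])
    c = np.sqrt(1.0 - phi * phi)
    for trip_slices in blocks:
        z_cols = []
        wU_parts = []
        wz_parts = []
        for t_idx in trip_slices:
            srel = rel_sd[strat_id[t_idx]]
            u = U[t_idx] / srel[:, None]
            ones = 1.0 / srel
            if ar1 and t_idx.size > 1:
                wu = np.empty_like(u)
                wu[0] = u[0]
                wu[1:] = (u[1:] - phi * u[:-1]) / c
                wo = np.empty_like(ones)
                wo[0] = ones[0]
                wo[1:] = (ones[1:] - phi * ones[:-1]) / c
                logdetV += (t_idx.size - 1) * np.log(1.0 - phi * phi)
            else:
                wu, wo = u, ones
            logdetV += 2.0 * np.sum(np.log(srel))
            wU_parts.append(wu)
            wz_parts.append(wo)
        wU = np.vstack(wU_parts)
        M_block = wU.T @ wU
        nz = int(has_ind) + (len(trip_slices) if has_trip else 0)
        if nz > 0:
            Zw = np.zeros((wU.shape[0], nz))
            row0 = 0
            for j, (wo, t_idx) in enumerate(zip(wz_parts, trip_slices)):
                rows = slice(row0, row0 + t_idx.size)
                if has_ind:
                    Zw[rows, 0] = wo
                if has_trip:
                    Zw[rows, int(has_ind) + j] = wo
                row0 += t_idx.size
            D = np.concatenate(
                [[g_ind] if has_ind else [], [g_trip] * len(trip_slices) if has_trip else []]
            )
            A = np.diag(1.0 / D) + Zw.T @ Zw
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return 1e12, None
            CzU = Zw.T @ wU
            B = np.linalg.solve(L, CzU)
            M_block = M_block - B.T @ B
            logdetV += 2.0 * np.sum(np.log(np.diag(L))) + np.sum(np.log(D))
        M += M_block
    Sxx = M[:p, :p]
    Sxy = M[:p, p]
    Syy = M[p, p]
    try:
        beta = np.linalg.solve(Sxx, Sxy)
    except np.linalg.LinAlgError:
        return 1e12, None
    q = Syy - Sxy @ beta
    if q <= 0:
        return 1e12, None
    s2 = q / n
    nll = 0.5 * (n * np.log(2.0 * np.pi) + n * np.log(s2) + n + logdetV)
    extras = {
        "beta": beta,
        "s2": s2,
        "Sxx": Sxx,
        "g_ind": g_ind,
        "g_trip": g_trip,
        "rel_sd": rel_sd,
        "phi": phi,
    }
    return nll, extras


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """ML fit of the structured mixed model defined by ``spec``.

    Data must contain the response, every fixed term, and the grouping /
    stage columns the spec references. Rows are used in their given order
    within trips (the AR(1) ordering).
    """
    y_raw = data[spec.response].to_numpy(dtype=float)
    if spec.transform == "arcsine" and (y_raw.min() < 0 or y_raw.max() > 1):
        raise ValueError("arcsine transform requires response in [0, 1]")
    if spec.transform == "sqrt" and y_raw.min() < 0:
        raise ValueError("sqrt transform requires non-negative response")
    y = _TRANSFORMS[spec.transform][0](y_raw)
    X, names, term_cols = _design(data, spec.fixed)

    if spec.variance_by_stage:
        strata = list(pd.unique(data[spec.stage_col].astype(str)))  # first-appearance order
        strat_id = data[spec.stage_col].astype(str).map({s: i for i, s in enumerate(strata)})
        strat_id = strat_id.to_numpy()
    else:
        strata = [""]
        strat_id = np.zeros(len(data), dtype=int)
    n_strata = len(strata)
    has_ind = spec.random in ("individual", "trip_in_individual")
    has_trip = spec.random == "trip_in_individual"
    blocks = _blocks(data, spec)
    layout = (blocks, X, y, strat_id, n_strata, has_ind, has_trip, spec.ar1_within_trip)

    n_theta = int(has_ind) + int(has_trip) + (n_strata - 1) + int(spec.ar1_within_trip)
    if n_theta == 0:
        nll, extras = _profiled_nll(np.empty(0), layout)
        if extras is None:
            raise np.linalg.LinAlgError("singular design or covariance")
    else:
        x0 = np.zeros(n_theta)
        if spec.ar1_within_trip:
            x0[-1] = np.arctanh(0.3)
        best = None
        for shift in (0.0, -1.5, 1.5):
            start = x0 + shift * (np.arange(n_theta) % 2 * 2 - 1) * 0.5
            res = optimize.minimize(
                lambda th: _profiled_nll(th, layout)[0],
                start,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 3000},
            )
            if best is None or res.fun < best.fun:
                best = res
        nll, extras = _profiled_nll(best.x, layout)
        if extras is None:
            raise np.linalg.LinAlgError("singular covariance at the optimum")

    beta = extras["beta"]
    s2 = extras["s2"]
    cov_beta = s2 * np.linalg.inv(extras["Sxx"])
    se = np.sqrt(np.diag(cov_beta))
    residual_sd = {
        strata[m]: float(np.sqrt(s2) * extras["rel_sd"][m]) for m in range(n_strata)
    }
    vc = {}
    if has_ind:
        vc["individual"] = float(s2 * extras["g_ind"])
    if has_trip:
        vc["trip"] = float(s2 * extras["g_trip"])
    n_params = X.shape[1] + 1 + n_theta
    return ModelFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        vc=vc,
        residual_sd=residual_sd,
        ar1_phi=float(extras["phi"]),
        log_likelihood=float(-nll),
        n_obs=len(data),
        n_params=n_params,
        term_columns=term_cols,
        cov_params=cov_beta,
    )


def lr_test(full: ModelFit, reduced: ModelFit) -> LRTest:
    """Likelihood-ratio test of nested ML fits on identical data."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are on different numbers of observations")
    df = full.n_params - reduced.n_params
    if df == 0:
        stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
        if abs(stat) > 1e-6:
            raise ValueError("models have equal parameter counts but different likelihoods")
        return LRTest(statistic=0.0, df=0, p_value=1.0)
    if df < 0:
        raise ValueError("reduced model is not nested in full (no fewer parameters)")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        raise ValueError("negative LR statistic: models do not appear nested")
    stat = max(stat, 0.0)
    return LRTest(statistic=float(stat), df=int(df), p_value=float(stats.chi2.sf(stat, df)))


def backward_select(data: pd.DataFrame, full_spec: ModelSpec, alpha: float = 0.05):
    """Backward stepwise deletion of fixed terms by LR tests.

    Repeatedly drops the least-significant term with p > alpha. Returns
    (final fit, audit DataFrame of every test in order).
    """
    from dataclasses import replace as _replace

    terms = list(full_spec.fixed)
    audit = []
    step = 0
    current = fit_mixed_model(data, _replace(full_spec, fixed=tuple(terms)))
    while terms:
        tests = []
        for term in terms:
            reduced_spec = _replace(full_spec, fixed=tuple(t for t in terms if t != term))
            reduced = fit_mixed_model(data, reduced_spec)
            tests.append((term, lr_test(current, reduced), reduced))
        term, worst, reduced = max(tests, key=lambda tr: tr[1].p_value)
        for t, lr, _ in tests:
            audit.append((step, t, lr.statistic, lr.df, lr.p_value, t == term and lr.p_value > alpha))
        if worst.p_value > alpha:
            terms.remove(term)
            current = reduced
            step += 1
        else:
            break
    trail = pd.DataFrame(audit, columns=["step", "term", "lr", "df", "p_value", "dropped"])
    return current, trail


@dataclass
class PoissonRateFit:
    """Dive-rate model: log-linear in stage with a log trip-hours offset."""

    params: pd.Series
    se: pd.Series
    rates_per_h: dict
    log_likelihood: float
    n_obs: int
    boundary: bool = False


def fit_poisson_rate(trips: pd.DataFrame, stage_col: str = "stage") -> PoissonRateFit:
    """Poisson model of dives per trip with exposure = trip duration.

    exp(coefficients) are hourly dive rates; ``rates_per_h`` holds the
    fitted rate for each stage.
    """
    import statsmodels.api as sm

    if (trips["duration_min"] <= 0).any():
        raise ValueError("zero or negative trip duration")
    y = trips["n_dives"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("negative dive counts")
    hours = trips["duration_min"].to_numpy(dtype=float) / 60.0
    stages = sorted(pd.unique(trips[stage_col].astype(str)))
    if y.sum() == 0:
        return PoissonRateFit(
            params=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            rates_per_h={s: 0.0 for s in stages},
            log_likelihood=0.0,
            n_obs=len(trips),
            boundary=True,
        )
    X = pd.DataFrame({"(Intercept)": np.ones(len(trips))})
    for lvl in stages[1:]:
        X[f"{stage_col}[{lvl}]"] = (trips[stage_col].astype(str) == lvl).astype(float)
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(hours)).fit()
    rates = {stages[0]: float(np.exp(fit.params.iloc[0]))}
    for i, lvl in enumerate(stages[1:], start=1):
        rates[lvl] = float(np.exp(fit.params.iloc[0] + fit.params.iloc[i]))
    return PoissonRateFit(
        params=fit.params,
        se=fit.bse,
        rates_per_h=rates,
        log_likelihood=float(fit.llf),
        n_obs=len(trips),
    )


def variance_components_explained(fit_without: ModelFit, fit_with: ModelFit) -> float:
    """Share of individual-level variance explained by an added covariate:
    (σ²_ind,without − σ²_ind,with) / σ²_ind,without, floored at 0."""
    if fit_without.n_obs != fit_with.n_obs:
        raise ValueError("fits are on different data")
    v0 = fit_without.vc.get("individual", 0.0)
    if v0 <= 0:
        raise ValueError("individual variance component is zero in the base fit")
    v1 = fit_with.vc.get("individual", 0.0)
    return max(0.0, (v0 - v1) / v0)


@dataclass
class GroupComparison:
    """Two-group GLS comparison: ML means, (optionally) per-group variances,
    LR tests of mean equality and of variance homogeneity."""

    groups: list
    means: dict
    sds_ml: dict
    mean_difference: float
    se_difference: float
    variance_ratio: float
    lr_mean: LRTest
    lr_variance: LRTest
    log_likelihood: float
    n_obs: int


def _norm_ll(n, s2):
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def compare_groups_gls(values, groups, stratified_variance: bool = True) -> GroupComparison:
    """Closed-form ML comparison of groups in mean and variance.

    Group means are sample means; group variances are ML (divisor n)
    variances. The mean-equality LR refits a common mean (iteratively
    reweighted under stratified variance); the homogeneity LR compares
    stratified against pooled residual variance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    split = {g: values[groups == g] for g in labels}
    for g, v in split.items():
        if v.size < 2 and stratified_variance:
            raise ValueError(f"group {g!r} has < 2 observations (stratified variance)")
    n = values.size
    means = {g: float(v.mean()) for g, v in split.items()}
    var_ml = {g: float(np.mean((v - means[g]) ** 2)) for g, v in split.items()}

    # full model: per-group mean; variance stratified or pooled
    resid2 = np.concatenate([(v - means[g]) ** 2 for g, v in split.items()])
    if stratified_variance:
        ll_full = sum(_norm_ll(v.size, var_ml[g]) for g, v in split.items())
    else:
        ll_full = _norm_ll(n, float(resid2.mean()))

    # reduced: common mean
    if stratified_variance:
        mu = float(values.mean())
        for _ in range(200):
            w = np.array([split[g].size / max(np.mean((split[g] - mu) ** 2), 1e-300) for g in labels])
            mu_new = float(np.sum(w * [split[g].mean() for g in labels]) / np.sum(w))
            if abs(mu_new - mu) < 1e-13:
                mu = mu_new
                break
            mu = mu_new
        ll_mean_red = sum(_norm_ll(split[g].size, float(np.mean((split[g] - mu) ** 2))) for g in labels)
    else:
        mu = float(values.mean())
        ll_mean_red = _norm_ll(n, float(np.mean((values - mu) ** 2)))
    stat_mean = max(0.0, 2.0 * (ll_full - ll_mean_red))
    df_mean = len(labels) - 1
    lr_mean = LRTest(stat_mean, df_mean, float(stats.chi2.sf(stat_mean, df_mean)))

    # homogeneity: per-group means, pooled variance
    ll_pooled = _norm_ll(n, float(resid2.mean()))
    ll_strat = sum(_norm_ll(v.size, var_ml[g]) for g, v in split.items())
    stat_var = max(0.0, 2.0 * (ll_strat - ll_pooled))
    df_var = len(labels) - 1
    lr_var = LRTest(stat_var, df_var, float(stats.chi2.sf(stat_var, df_var)))

    g1, g2 = labels[0], labels[-1]
    se_diff = float(np.sqrt(var_ml[g1] / split[g1].size + var_ml[g2] / split[g2].size))
    return GroupComparison(
        groups=labels,
        means=means,
        sds_ml={g: float(np.sqrt(v)) for g, v in var_ml.items()},
        mean_difference=float(means[g2] - means[g1]),
        se_difference=se_diff,
        variance_ratio=float(var_ml[g2] / var_ml[g1]),
        lr_mean=lr_mean,
        lr_variance=lr_var,
        log_likelihood=float(ll_full),
        n_obs=n,
    )
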