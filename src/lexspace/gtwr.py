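"""Geographically and Temporally Weighted Regression (GTWR).

At each observation i a weighted least-squares fit

    beta_i = (X' W_i X)^{-1} X' W_i y

is solved, where W_i is diagonal with kernel weights decaying in the combined
space-time distance d = sqrt(dx^2 + dy^2 + tau^2 dt^2) between district
centroids (metric projection) and years. ``tau`` (meters per year) folds the
temporal separation into the same metric as space; the bandwidth ``h`` is
chosen by leave-one-out cross-validation with the self-weight forced to zero.

Diagnostics follow the locally-weighted-regression conventions: the effective
number of parameters ENP is the trace of the hat matrix (hat row
h_i = x_i (X'W_iX)^{-1} X'W_i), and adjusted R^2 uses n − ENP − 1 residual
degrees of freedom. The per-predictor summary reports the mean local
coefficient with a normal-approximation 95% CI on that mean (percentile
option available) plus the quartiles of the local distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

#: resource terms of the full (per-resource) model, in panel-column order
FULL_RESOURCE_TERMS = (
    "clin_psych_clinic", "couns_psych_clinic", "soc_worker_clinic",
    "psychiatry_clinic", "clin_psych_hosp", "couns_psych_hosp",
    "soc_worker_hosp", "beds_acute", "beds_chronic", "beds_intensive",
    "psychiatry_hosp", "psychiatry_doctor",
)

#: aggregate terms of the summary model
SUMMARY_RESOURCE_TERMS = ("psych_sw", "psychiatry", "beds", "psychiatry_doctor")

COVARIATE_TERMS = ("low_income_households", "college_share", "year_centered")


@dataclass
class GTWRConfig:
    kernel: str = "gaussian"          # gaussian | bisquare
    bandwidth: float | None = None    # meters; None → cross-validate
    tau: float = 0.0                  # meters per year of temporal separation
    bandwidth_grid: tuple[float, ...] | None = None
    tau_grid: tuple[float, ...] = (0.0,)
    cv_exclude_self: bool = True      # fixed true; kept explicit for the record
    ridge_scale: float = 1e-8
    ci_method: str = "normal"         # normal | percentile

    def __post_init__(self):
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class GTWRFit:
    local_beta: np.ndarray            # (n, p)
    yhat: np.ndarray
    residuals: np.ndarray
    enp: float
    r2: float
    adj_r2: float                     # NaN when n - ENP - 1 <= 0 (flagged)
    bandwidth: float
    tau: float
    kernel: str
    term_names: list[str]
    summary: pd.DataFrame = field(repr=False, default=None)
    adj_r2_undefined: bool = False
    n_ridge_fallbacks: int = 0


@dataclass
class CVResult:
    bandwidth: float
    tau: float
    curve: pd.DataFrame               # columns h, tau, score


def st_distance(point_i, point_j, tau: float) -> float:
    """Space-time distance sqrt(dx^2 + dy^2 + tau^2 dt^2)."""
    dx = point_i[0] - point_j[0]
    dy = point_i[1] - point_j[1]
    dt = point_i[2] - point_j[2]
    return float(np.sqrt(dx * dx + dy * dy + tau * tau * dt * dt))


def kernel_weight(d, h: float, kernel: str = "gaussian"):
    """Kernel weight in [0, 1]: gaussian exp(−(d/h)²) or bisquare (1−(d/h)²)²·1{d<h}."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    u = d / h
    if kernel == "gaussian":
        w = np.exp(-(u**2))
    elif kernel == "bisquare":
        w = np.where(u < 1, (1 - u**2) ** 2, 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return float(w) if w.ndim == 0 else w


def _weight_matrix(coords: np.ndarray, h: float, tau: float, kernel: str) -> np.ndarray:
    xy = coords[:, :2]
    t = coords[:, 2]
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1) \
        + tau**2 * (t[:, None] - t[None, :]) ** 2
    return kernel_weight(np.sqrt(d2), h, kernel)


def _batched_wls(X: np.ndarray, y: np.ndarray, K: np.ndarray, ridge_scale: float
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve beta_i = (X'W_iX)^{-1} X'W_iy for every row of K at once.

    Returns (betas (n,p), AinvX (n,p) = (X'W_iX)^{-1} x_i, n_ridge_fallbacks).
    """
    n, p = X.shape
    M = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    A = (K @ M).reshape(n, p, p)                     # X'W_iX per fit point
    B = K @ (X * y[:, None])                         # X'W_iy per fit point
    n_ridge = 0
    try:
        betas = np.linalg.solve(A, B[..., None])[..., 0]
        ainv_x = np.linalg.solve(A, X[..., None])[..., 0]
    except np.linalg.LinAlgError:
        betas = np.empty((n, p))
        ainv_x = np.empty((n, p))
        for i in range(n):
            Ai = A[i]
            try:
                betas[i] = np.linalg.solve(Ai, B[i])
                ainv_x[i] = np.linalg.solve(Ai, X[i])
            except np.linalg.LinAlgError:
                lam = ridge_scale * np.trace(Ai) / p
                Ai = Ai + lam * np.eye(p)
                betas[i] = np.linalg.solve(Ai, B[i])
                ainv_x[i] = np.linalg.solve(Ai, X[i])
                n_ridge += 1
        if n_ridge:
            log.warning("ridge fallback applied at %d fit points", n_ridge)
    return betas, ainv_x, n_ridge


def summarize_local(local_beta: np.ndarray, term_names, ci_method: str = "normal"
                    ) -> pd.DataFrame:
    """Paper-style per-predictor summary of the local coefficient surfaces.

    mean, 95% CI on the mean (normal approximation by default, percentile of
    the local distribution as the alternative), quartiles, and significance
    stars from the CI-vs-zero z-test (* p<0.05, ** p<0.01, *** p<0.001).
    """
    n = local_beta.shape[0]
    rows = []
    for j, name in enumerate(term_names):
        b = local_beta[:, j]
        mean = b.mean()
        se = b.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        if ci_method == "normal":
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        elif ci_method == "percentile":
            lo, hi = np.percentile(b, [2.5, 97.5])
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        if np.isfinite(se) and se > 0:
            pval = float(2 * stats.norm.sf(abs(mean / se)))
        else:
            pval = np.nan
        stars = ("***" if pval < 0.001 else "**" if pval < 0.01
                 else "*" if pval < 0.05 else "")
        rows.append({"term": name, "mean": mean, "lo95": lo, "hi95": hi,
                     "q25": float(np.percentile(b, 25)),
                     "median": float(np.percentile(b, 50)),
                     "q75": float(np.percentile(b, 75)),
                     "p": pval, "stars": stars})
    return pd.DataFrame(rows)


def gtwr_fit(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
             config: GTWRConfig, term_names=None) -> GTWRFit:
    """Fit the GTWR model at every observation point.

    ``X`` is the design matrix (include the intercept column explicitly),
    ``coords`` the (x, y, t) rows in a metric projection and years. The
    bandwidth must be set in ``config`` (use :func:`cv_bandwidth` first when
    it is not).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if config.bandwidth is None:
        raise ValueError("config.bandwidth is unset; run cv_bandwidth first")
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]

    K = _weight_matrix(coords, config.bandwidth, config.tau, config.kernel)
    betas, ainv_x, n_ridge = _batched_wls(X, y, K, config.ridge_scale)
    yhat = (X * betas).sum(axis=1)
    resid = y - yhat
    hii = (X * ainv_x).sum(axis=1) * np.diag(K)      # w_ii = kernel(0) = 1
    enp = float(hii.sum())
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1 - rss / tss if tss > 0 else np.nan
    dof = n - enp - 1
    adj_undef = dof <= 0
    adj_r2 = np.nan if adj_undef else 1 - (1 - r2) * (n - 1) / dof
    if adj_undef:
        log.warning("adjusted R^2 undefined: n - ENP - 1 = %.2f <= 0", dof)
    return GTWRFit(local_beta=betas, yhat=yhat, residuals=resid, enp=enp,
                   r2=r2, adj_r2=adj_r2, bandwidth=config.bandwidth,
                   tau=config.tau, kernel=config.kernel,
                   term_names=list(term_names),
                   summary=summarize_local(betas, term_names, config.ci_method),
                   adj_r2_undefined=adj_undef, n_ridge_fallbacks=n_ridge)


def loocv_score(X, y, coords, h: float, tau: float, kernel: str,
                ridge_scale: float = 1e-8) -> float:
    """Leave-one-out CV score sum_i (y_i − yhat_(i))² with w_ii forced to 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = _weight_matrix(np.asarray(coords, float), h, tau, kernel)
    np.fill_diagonal(K, 0.0)
    try:
        betas, _, _ = _batched_wls(X, y, K, ridge_scale)
    except np.linalg.LinAlgError:
        return float("inf")
    yhat = (X * betas).sum(axis=1)
    score = float(((y - yhat) ** 2).sum())
    return score if np.isfinite(score) else float("inf")


def cv_bandwidth(X, y, coords, config: GTWRConfig) -> CVResult:
    """Grid search of (h, tau) by leave-one-out cross-validation.

    Ties go to the smaller bandwidth. Raises when every grid point yields a
    non-finite score (advising a larger bandwidth floor).
    """
    if not config.bandwidth_grid:
        raise ValueError("config.bandwidth_grid is empty")
    rows = []
    for tau in config.tau_grid:
        for h in sorted(config.bandwidth_grid):
            rows.append({"h": float(h), "tau": float(tau),
                         "score": loocv_score(X, y, coords, h, tau, config.kernel,
                                              config.ridge_scale)})
    curve = pd.DataFrame(rows)
    finite = curve[np.isfinite(curve["score"])]
    if finite.empty:
        raise ValueError("all CV scores non-finite; raise the bandwidth floor "
                         "(weights vanish at every candidate bandwidth)")
    best_score = finite["score"].min()
    best = finite[finite["score"] == best_score].sort_values(["h", "tau"]).iloc[0]
    return CVResult(bandwidth=float(best["h"]), tau=float(best["tau"]), curve=curve)


def default_bandwidth_grid(coords: np.ndarray, fractions=(0.05, 0.1, 0.2, 0.4, 0.8)
                           ) -> tuple[float, ...]:
    """Candidate bandwidths as fractions of the maximum pairwise spatial distance."""
    xy = np.asarray(coords, float)[:, :2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    dmax = float(np.hypot(*(hi - lo)))
    return tuple(f * dmax for f in fractions)


def build_design(derived: pd.DataFrame, districts: pd.DataFrame,
                 outcome: str, category: str, predictors: str = "full"
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Model matrix, outcome and (x, y, t) coordinates for the table models.

    ``predictors='full'`` uses the 12 per-resource densities; ``'summary'``
    the four aggregate densities; both add low-income households, the
    college-degree share, the centered year, and an intercept. Rows whose
    outcome is undefined (zero population or zero category cases) are dropped
    and reported in the returned dropped-rows table.
    """
    if predictors == "full":
        terms = [f"{t}_per10k" for t in FULL_RESOURCE_TERMS]
    elif predictors == "summary":
        terms = [f"{t}_per10k" for t in SUMMARY_RESOURCE_TERMS]
    else:
        raise ValueError("predictors must be 'full' or 'summary'")
    terms = terms + list(COVARIATE_TERMS)
    ycol = f"{outcome}_{category}"
    if ycol not in derived.columns:
        raise ValueError(f"unknown outcome column {ycol!r}")
    df = derived.merge(districts[["district_id", "cx", "cy"]], on="district_id",
                       how="left", validate="many_to_one")
    if df["cx"].isna().any():
        missing = sorted(df.loc[df["cx"].isna(), "district_id"].unique())
        raise ValueError(f"districts missing geometry: {missing}")
    keep = np.isfinite(df[ycol].to_numpy(dtype=float))
    for t in terms:
        keep &= np.isfinite(df[t].to_numpy(dtype=float))
    dropped = df.loc[~keep, ["district_id", "year"]]
    df = df.loc[keep]
    X = np.column_stack([df[t].to_numpy(dtype=float) for t in terms]
                        + [np.ones(len(df))])
    y = df[ycol].to_numpy(dtype=float)
    coords = df[["cx", "cy", "year"]].to_numpy(dtype=float)
    return X, y, coords, terms + ["intercept"], dropped


def fit_table_models(derived: pd.DataFrame, districts: pd.DataFrame,
                     outcome: str = "crime_rate", category: str = "all",
                     predictors: str = "full",
                     config: GTWRConfig | None = None) -> GTWRFit:
    """Fit one paper-style table model on a derived panel.

    Cross-validates the bandwidth when the config leaves it unset, then fits
    GTWR and returns the fit with its per-predictor summary table.
    """
    config = config or GTWRConfig()
    X, y, coords, names, dropped = build_design(derived, districts, outcome,
                                                category, predictors)
    if len(dropped):
        log.info("dropped %d rows with undefined %s_%s", len(dropped), outcome, category)
    if config.bandwidth is None:
        grid = config.bandwidth_grid or default_bandwidth_grid(coords)
        cv = cv_bandwidth(X, y, coords, GTWRConfig(
            kernel=config.kernel, bandwidth_grid=tuple(grid),
            tau_grid=config.tau_grid, ridge_scale=config.ridge_scale))
        config = GTWRConfig(kernel=config.kernel, bandwidth=cv.bandwidth,
                            tau=cv.tau, ridge_scale=config.ridge_scale,
                            ci_method=config.ci_method)
    return gtwr_fit(X, y, coords, config, term_names=names)


@dataclass
class SLXResult:
    table: pd.DataFrame               # term, coef, se, t, p
    dropped_lags: list[str]
    model: object = field(repr=False, default=None)


def row_standardize(W: np.ndarray) -> np.ndarray:
    """Row-standardize a (zero-diagonal) spatial weight matrix."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    rs = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rs > 0, W / rs, 0.0)
    return out


def slx_ols(X: np.ndarray, y: np.ndarray, W: np.ndarray, term_names=None) -> SLXResult:
    """Spatial-lag-of-X OLS: augment the design with WX and fit globally.

    ``W`` must be row-standardized with zero diagonal (use
    :func:`row_standardize`). Intercept columns are not lagged; lagged
    columns that are constant (e.g. the lag of a constant under row
    standardization) are dropped with a warning. Rank deficiency raises an
    error naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    is_const = [np.ptp(X[:, j]) == 0 for j in range(p)]
    cols = [X]
    names = list(term_names)
    dropped = []
    WX = W @ X
    for j in range(p):
        if is_const[j]:
            continue
        lag = WX[:, j]
        if np.ptp(lag) < 1e-12:
            dropped.append(f"W.{term_names[j]}")
            log.warning("dropped constant lagged column W.%s (collinear with "
                        "intercept)", term_names[j])
            continue
        cols.append(lag[:, None])
        names.append(f"W.{term_names[j]}")
    Xaug = np.hstack(cols)
    rank = np.linalg.matrix_rank(Xaug)
    if rank < Xaug.shape[1]:
        corr = np.corrcoef(Xaug, rowvar=False)
        pairs = [(names[a], names[b])
                 for a in range(len(names)) for b in range(a + 1, len(names))
                 if abs(corr[a, b]) > 1 - 1e-10]
        raise ValueError(f"rank-deficient SLX design; collinear columns: "
                         f"{pairs or names}")
    res = sm.OLS(y, Xaug).fit()
    table = pd.DataFrame({"term": names, "coef": res.params, "se": res.bse,
                          "t": res.tvalues, "p": res.pvalues})
    return SLXResult(table=table, dropped_lags=dropped, model=res)
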