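"""Multivariate statistics: kernel PLSR, jackknife inference, MANCOVA,
adjusted group means, and quantile LOESS normative curves.

The regression layer predicts the 24 regional artery measurements from nine
risk factors (ICV, sex, age, BMI, WHR, systolic blood pressure, heart rate,
drinks category, smoking years).  Responses are min-max normalized to [0, 1]
and predictors centered and scaled; both transforms are re-estimated inside
every leave-one-out fold so the held-out row never leaks into them.  PLSR uses
the kernel algorithm of Dayal & MacGregor, which needs only the cross-product
matrices X'X and X'Y — that makes the n leave-one-out refits cheap via
rank-one downdates of the sufficient statistics.

Coefficient p-values come from the jackknife: the variance of the coefficient
over the n leave-one-out refits with the Tukey (n-1)/n factor, referred to a
t distribution with n-1 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import t as t_dist

__all__ = [
    "Preprocessor",
    "PLSRModel",
    "CVResult",
    "JackknifeResult",
    "MancovaResult",
    "preprocess",
    "fit_kernel_plsr",
    "loo_cv",
    "jackknife_pvalues",
    "mancova",
    "adjusted_group_means",
    "quantile_loess",
    "BONFERRONI_N",
    "bonferroni_threshold",
]

log = logging.getLogger("vesselmorph")

#: Number of pairwise post-hoc comparisons the Bonferroni correction divides by.
BONFERRONI_N = 24


def bonferroni_threshold(alpha: float = 0.05, n: int = BONFERRONI_N) -> float:
    """Per-comparison significance cut, e.g. 0.05 / 24 ~ 0.002."""
    return alpha / n


# --- Preprocessing -----------------------------------------------------------

@dataclass
class Preprocessor:
    """Column transforms: predictors centered/scaled, responses min-max to [0, 1].

    Held-out rows outside the training range map outside [0, 1]; values are
    deliberately not clamped.
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def inverse_y(self, Yn: np.ndarray) -> np.ndarray:
        return np.asarray(Yn, dtype=float) * (self.y_max - self.y_min) + self.y_min


def preprocess(
    X: np.ndarray,
    Y: np.ndarray,
    fit_rows: np.ndarray | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> tuple[Preprocessor, np.ndarray, np.ndarray]:
    """Fit transforms on ``fit_rows`` (default: all) and apply to all rows."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rows = np.arange(len(X)) if fit_rows is None else np.asarray(fit_rows)
    if len(rows) == 0:
        raise ValueError("fit_rows is empty")
    Xf, Yf = X[rows], Y[rows]
    sd = Xf.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        name = x_names[bad[0]] if x_names else f"column {bad[0]}"
        raise ValueError(f"zero-variance predictor on fit rows: {name}")
    ymin, ymax = Yf.min(axis=0), Yf.max(axis=0)
    badr = np.flatnonzero(ymax - ymin <= 0)
    if badr.size:
        name = y_names[badr[0]] if y_names else f"column {badr[0]}"
        raise ValueError(f"constant response on fit rows: {name}")
    prep = Preprocessor(x_mean=Xf.mean(axis=0), x_sd=sd, y_min=ymin, y_max=ymax)
    return prep, prep.transform_x(X), prep.transform_y(Y)


# --- Kernel PLSR -------------------------------------------------------------

def _kernelpls_from_crossprods(
    XtX: np.ndarray, XtY: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Kernel PLS (Dayal & MacGregor, cross-product form).

    Returns (W, P, Q, R, betas) where ``betas[a]`` is the (p, q) coefficient
    matrix of the model with a+1 components.  If the cross-covariance deflates
    to numerically zero before ``k`` components, the remaining components are
    frozen (coefficients stop changing).
    """
    p, q = XtY.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((q, k))
    R = np.zeros((p, k))
    betas = np.zeros((k, p, q))
    S = XtY.copy()
    scale0 = max(np.linalg.norm(S), 1.0)
    B = np.zeros((p, q))
    for a in range(k):
        if q == 1:
            w = S[:, 0].copy()
        elif q <= p:
            C = S.T @ S
            vals, vecs = np.linalg.eigh(C)
            w = S @ vecs[:, -1]
        else:
            C = S @ S.T
            vals, vecs = np.linalg.eigh(C)
            w = vecs[:, -1]
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * scale0:
            betas[a:] = B
            break
        w /= nw
        r = w.copy()
        for j in range(a):
            r -= (P[:, j] @ w) * R[:, j]
        tt = float(r @ XtX @ r)
        if tt <= 1e-13 * max(np.trace(XtX), 1.0):
            betas[a:] = B
            break
        p_vec = XtX @ r / tt
        q_vec = S.T @ r / tt
        S = S - tt * np.outer(p_vec, q_vec)
        W[:, a], P[:, a], Q[:, a], R[:, a] = w, p_vec, q_vec, r
        B = B + np.outer(r, q_vec)
        betas[a] = B
    return W, P, Q, R, betas


@dataclass
class PLSRModel:
    """A fitted kernel-PLSR model on preprocessed scales.

    The fit centers both matrices internally (as the reference kernel-PLS
    implementation does), so predictions carry an intercept:
    ``yhat = y_center + (X - x_center) @ beta``.
    """

    k: int
    beta: np.ndarray            # (p, q), preprocessed scales
    weights: np.ndarray         # W (p, k)
    loadings: np.ndarray        # P (p, k)
    y_loadings: np.ndarray      # Q (q, k)
    rotations: np.ndarray       # R (p, k): T = Xc @ R
    x_center: np.ndarray = None
    y_center: np.ndarray = None
    scores: np.ndarray | None = None      # (n, k)
    preprocessor: Preprocessor | None = None

    def predict(self, Xp: np.ndarray) -> np.ndarray:
        """Predict normalized responses from preprocessed predictors."""
        return (np.asarray(Xp, dtype=float) - self.x_center) @ self.beta + self.y_center


def fit_kernel_plsr(Xp: np.ndarray, Yp: np.ndarray, k: int) -> PLSRModel:
    """Fit kernel PLSR with ``k`` components on preprocessed matrices.

    ``k`` must not exceed the rank of the centered predictor matrix.
    """
    Xp = np.asarray(Xp, dtype=float)
    Yp = np.asarray(Yp, dtype=float)
    if Yp.ndim == 1:
        Yp = Yp[:, None]
    xbar = Xp.mean(axis=0)
    ybar = Yp.mean(axis=0)
    Xc = Xp - xbar
    Yc = Yp - ybar
    rank = np.linalg.matrix_rank(Xc)
    if not 1 <= k <= rank:
        raise ValueError(f"k must be in [1, rank(X)] = [1, {rank}], got {k}")
    XtX = Xc.T @ Xc
    XtY = Xc.T @ Yc
    W, P, Q, R, betas = _kernelpls_from_crossprods(XtX, XtY, k)
    return PLSRModel(
        k=k, beta=betas[k - 1], weights=W[:, :k], loadings=P[:, :k],
        y_loadings=Q[:, :k], rotations=R[:, :k],
        x_center=xbar, y_center=ybar, scores=Xc @ R[:, :k],
    )


# --- Leave-one-out machinery -------------------------------------------------

def _loo_folds(X: np.ndarray, Y: np.ndarray):
    """Yield per-fold preprocessed cross-products via rank-one downdates.

    For fold i (row i held out) yields ``(i, XtXp, XtYp, xh, yh, ybar)``
    where the cross-products are of the centered/scaled training X against the
    min-max-normalized training Y (centering X makes them equal to the doubly
    centered cross-products), ``xh, yh`` are the held-out row on the fold's
    preprocessed scales, and ``ybar`` is the normalized-response training mean
    (the model intercept).
    """
    n, p = X.shape
    q = Y.shape[1]
    Sx = X.sum(axis=0)
    Sxx = X.T @ X
    Sxy = X.T @ Y
    Sy = Y.sum(axis=0)
    # two smallest / largest per response column, for O(1) fold min/max
    ord0 = np.argsort(Y, axis=0, kind="stable")
    imin1, imin2 = ord0[0], ord0[1]
    imax1, imax2 = ord0[-1], ord0[-2]
    cols = np.arange(q)
    vmin1, vmin2 = Y[imin1, cols], Y[imin2, cols]
    vmax1, vmax2 = Y[imax1, cols], Y[imax2, cols]
    ni = n - 1
    for i in range(n):
        xi, yi = X[i], Y[i]
        Sx_i = Sx - xi
        Sy_i = Sy - yi
        mu = Sx_i / ni
        Sxx_i = Sxx - np.outer(xi, xi)
        var = (np.diag(Sxx_i) - ni * mu**2) / (ni - 1)
        if (var <= 1e-15).any():
            j = int(np.flatnonzero(var <= 1e-15)[0])
            raise ValueError(
                f"fold {i}: predictor column {j} has zero variance on training rows"
            )
        sd = np.sqrt(var)
        ymin = np.where(imin1 == i, vmin2, vmin1)
        ymax = np.where(imax1 == i, vmax2, vmax1)
        yrange = ymax - ymin
        if (yrange <= 0).any():
            j = int(np.flatnonzero(yrange <= 0)[0])
            raise ValueError(
                f"fold {i}: response column {j} is constant on training rows"
            )
        XtXc = Sxx_i - ni * np.outer(mu, mu)
        XtYc = (Sxy - np.outer(xi, yi)) - np.outer(mu, Sy_i)
        XtXp = XtXc / np.outer(sd, sd)
        XtYp = XtYc / sd[:, None] / yrange[None, :]
        xh = (xi - mu) / sd
        yh = (yi - ymin) / yrange
        ybar = (Sy_i / ni - ymin) / yrange
        yield i, XtXp, XtYp, xh, yh, ybar, sd, yrange


@dataclass
class CVResult:
    """Leave-one-out RMSE per (component count, response) and the chosen k."""

    rmse: np.ndarray            # (k_max, q), normalized response scale
    chosen_k: int
    response_names: list[str] | None = None

    def mean_rmse(self) -> np.ndarray:
        return self.rmse.mean(axis=1)


def loo_cv(X: np.ndarray, Y: np.ndarray, k_max: int) -> CVResult:
    """Leave-one-out cross-validation over component counts 1..k_max.

    Preprocessing and the PLSR fit are both re-estimated on each fold's
    training rows; the held-out row is predicted on the fold's normalized
    scale.  ``chosen_k`` minimizes the response-averaged RMSE, ties going to
    the smaller k.  The result is invariant to row order.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 rows")
    if not 1 <= k_max <= p:
        raise ValueError(f"k_max must be in [1, {p}], got {k_max}")
    q = Y.shape[1]
    sq = np.zeros((k_max, q))
    for i, XtXp, XtYp, xh, yh, ybar, _, _ in _loo_folds(X, Y):
        try:
            _, _, _, _, betas = _kernelpls_from_crossprods(XtXp, XtYp, k_max)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"PLS fit failed on fold {i}: {e}") from e
        preds = ybar[None, :] + np.einsum("p,kpq->kq", xh, betas)
        sq += (preds - yh[None, :]) ** 2
    rmse = np.sqrt(sq / n)
    chosen = int(np.argmin(rmse.mean(axis=1))) + 1
    return CVResult(rmse=rmse, chosen_k=chosen)


@dataclass
class JackknifeResult:
    """Coefficient inference from the leave-one-out refits."""

    beta: np.ndarray            # (p, q) full-data coefficients (preprocessed scales)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    predictor_names: list[str] | None = None
    response_names: list[str] | None = None

    @property
    def sig05(self) -> np.ndarray:
        return self.p < 0.05

    @property
    def sig01(self) -> np.ndarray:
        return self.p < 0.01

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (predictor, response)."""
        p_, q_ = self.beta.shape
        preds = self.predictor_names or [f"x{i}" for i in range(p_)]
        resps = self.response_names or [f"y{j}" for j in range(q_)]
        rows = []
        for i, pn in enumerate(preds):
            for j, rn in enumerate(resps):
                rows.append({
                    "predictor": pn, "response": rn,
                    "beta": self.beta[i, j], "se": self.se[i, j],
                    "t": self.t[i, j], "p": self.p[i, j],
                    "sig_0.05": bool(self.p[i, j] < 0.05),
                    "sig_0.01": bool(self.p[i, j] < 0.01),
                })
        return pd.DataFrame(rows)


def jackknife_pvalues(
    X: np.ndarray,
    Y: np.ndarray,
    k: int,
    predictor_names: list[str] | None = None,
    response_names: list[str] | None = None,
) -> JackknifeResult:
    """Jackknife t-tests for the PLSR coefficients.

    Variance over the n leave-one-out coefficient estimates with the Tukey
    (n-1)/n factor; two-sided p from a t distribution with n-1 df.  Because
    the min-max/centering transforms are re-estimated inside each fold, the
    fold coefficients are first mapped to the raw-units scale (response units
    per predictor unit, invariant to the fold transforms) before the variance
    is taken; the standard error is then mapped back to the full-data
    normalized scale, so beta, se and t are mutually consistent.  Cells with
    zero jackknife variance but a nonzero coefficient get a p-value at the
    machine floor with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 10:
        raise ValueError("jackknife inference needs at least 10 rows")
    q = Y.shape[1]
    prep, Xp, Yp = preprocess(X, Y)
    full = fit_kernel_plsr(Xp, Yp, k)
    beta_sum = np.zeros((p, q))
    beta_sq = np.zeros((p, q))
    for i, XtXp, XtYp, xh, yh, ybar, sd, yrange in _loo_folds(X, Y):
        _, _, _, _, betas = _kernelpls_from_crossprods(XtXp, XtYp, k)
        b = betas[k - 1] * yrange[None, :] / sd[:, None]   # raw-units scale
        beta_sum += b
        beta_sq += b * b
    mean = beta_sum / n
    var = (n - 1) / n * (beta_sq - n * mean**2)
    var = np.maximum(var, 0.0)
    # back to the full-data normalized scale
    se = np.sqrt(var) * prep.x_sd[:, None] / (prep.y_max - prep.y_min)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, full.beta / np.where(se > 0, se, 1.0), np.inf * np.sign(full.beta))
    pval = 2.0 * t_dist.sf(np.abs(tval), df=n - 1)
    degenerate = (se == 0) & (full.beta != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} coefficient(s) have zero jackknife variance "
            "with a nonzero estimate; p reported at the machine floor",
            stacklevel=2,
        )
        pval = np.where(degenerate, np.finfo(float).tiny, pval)
    pval = np.where((se == 0) & (full.beta == 0), 1.0, pval)
    return JackknifeResult(
        beta=full.beta, se=se, t=tval, p=pval, df=n - 1,
        predictor_names=predictor_names, response_names=response_names,
    )


# --- MANCOVA -----------------------------------------------------------------

@dataclass
class MancovaResult:
    """Omnibus Wilks' lambda for the group factor plus Bonferroni post-hocs."""

    wilks_lambda: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    posthoc: pd.DataFrame       # response, p_raw, p_bonferroni, significant
    adjusted_means: pd.DataFrame
    bonferroni_n: int = BONFERRONI_N


def _as_2d(Y) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), list(Y.columns)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, [f"y{j}" for j in range(Y.shape[1])]


def mancova(Y, group, covariates) -> MancovaResult:
    """Group comparison of multiple responses adjusting for covariates.

    Wilks' lambda (with Rao's F approximation) for the binary ``group`` factor
    after adjusting for the covariates (age and sex in the reference
    analysis); post-hoc per-response ANCOVAs with the same covariates,
    Bonferroni-corrected with a fixed factor of ``BONFERRONI_N`` = 24:
    significance requires raw p < 0.05 / 24 ~ 0.002.

    With a single response, Wilks' lambda reduces exactly to the ANCOVA
    F-test for the group term.
    """
    from scipy.stats import f as f_dist

    Ymat, ynames = _as_2d(Y)
    Cmat, cnames = _as_2d(covariates)
    g = np.asarray(group, dtype=float).ravel()
    n, q = Ymat.shape
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError(f"group must be binary, found levels {groups}")
    if n <= q + 3:
        raise ValueError(f"need n > q + 3 (= {q + 3}) rows, got {n}")
    exog = np.column_stack([np.ones(n), Cmat, (g == groups[1]).astype(float)])

    def _resid_sscp(A: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(A, Ymat, rcond=None)
        R = Ymat - A @ coef
        return R.T @ R

    E = _resid_sscp(exog)                 # error SSCP, full model
    H = _resid_sscp(exog[:, :-1]) - E     # hypothesis SSCP for the group term
    sign, logdet_E = np.linalg.slogdet(E)
    sign2, logdet_EH = np.linalg.slogdet(E + H)
    if sign <= 0 or sign2 <= 0:
        raise ValueError(
            "singular within-group covariance; consider reducing the response set"
        )
    wilks = float(np.exp(logdet_E - logdet_EH))
    # Rao's F approximation (hypothesis df = 1 for a binary factor)
    qh = 1.0
    v = n - exog.shape[1]                 # error df
    s = np.sqrt((q**2 * qh**2 - 4) / (q**2 + qh**2 - 5)) if (q**2 + qh**2 - 5) > 0 else 1.0
    m = v - (q - qh + 1) / 2.0
    dfn = q * qh
    dfd = m * s - q * qh / 2.0 + 1.0
    lam_s = wilks ** (1.0 / s)
    fval = (1.0 - lam_s) / lam_s * dfd / dfn
    pval = float(f_dist.sf(fval, dfn, dfd))

    import statsmodels.api as sm

    cut = bonferroni_threshold()
    rows = []
    for j, name in enumerate(ynames):
        fit = sm.OLS(Ymat[:, j], exog).fit()
        p_raw = float(fit.pvalues[-1])
        rows.append({
            "response": name,
            "p_raw": p_raw,
            "p_bonferroni": min(1.0, BONFERRONI_N * p_raw),
            "significant": p_raw < cut,
        })
    posthoc = pd.DataFrame(rows)
    adj = adjusted_group_means(Y, group, covariates)
    return MancovaResult(
        wilks_lambda=wilks, f_value=fval, df_num=dfn, df_den=dfd,
        p_value=pval, posthoc=posthoc, adjusted_means=adj,
    )


def adjusted_group_means(Y, group, covariates) -> pd.DataFrame:
    """Least-squares (covariate-adjusted) group means with standard errors.

    Each response is fitted by OLS on [1, covariates, group]; group means are
    the fitted values at the sample covariate means for each group level.
    """
    import statsmodels.api as sm

    Ymat, ynames = _as_2d(Y)
    Cmat, _ = _as_2d(covariates)
    g = np.asarray(group, dtype=float).ravel()
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError(f"group must be binary, found levels {groups}")
    n = len(g)
    exog = np.column_stack([np.ones(n), Cmat, (g == groups[1]).astype(float)])
    cbar = Cmat.mean(axis=0)
    rows = []
    for j, name in enumerate(ynames):
        fit = sm.OLS(Ymat[:, j], exog).fit()
        rec = {"response": name}
        for lev, glab in zip(groups, (0, 1)):
            c = np.concatenate([[1.0], cbar, [float(glab)]])
            rec[f"mean_group{int(lev)}"] = float(c @ fit.params)
            rec[f"se_group{int(lev)}"] = float(np.sqrt(c @ fit.cov_params() @ c))
        rows.append(rec)
    return pd.DataFrame(rows)


# --- Quantile LOESS ----------------------------------------------------------

def _local_quantile_fit(
    dx: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float
) -> float:
    """Local-linear quantile fit at dx = 0: minimize tricube-weighted pinball
    loss; returns the intercept.  Solved exactly as a linear program."""
    m = len(y)
    if np.ptp(dx) == 0:
        # degenerate window: weighted sample quantile
        order = np.argsort(y)
        cw = np.cumsum(w[order])
        idx = np.searchsorted(cw, tau * cw[-1])
        return float(y[order][min(idx, m - 1)])
    # variables: a, b, u (m), v (m)
    c = np.concatenate([[0.0, 0.0], tau * w, (1.0 - tau) * w])
    A = sparse.hstack([
        sparse.csc_matrix(np.column_stack([np.ones(m), dx])),
        sparse.eye(m, format="csc"),
        -sparse.eye(m, format="csc"),
    ], format="csc")
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * m)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"quantile fit LP failed: {res.message}")
    return float(res.x[0])


def quantile_loess(
    x: np.ndarray,
    y: np.ndarray,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
    span: float = 0.75,
    grid: np.ndarray | None = None,
    min_points: int = 5,
) -> pd.DataFrame:
    """Age-conditional quantile curves by local-linear quantile regression.

    At each grid point the span-nearest neighbours are tricube-weighted and a
    local-linear fit minimizes the pinball loss for each quantile.  Windows
    with fewer than ``min_points`` contributing points yield a missing value.
    Curves are re-sorted per grid point afterwards so quantiles never cross.

    Returns a DataFrame with column ``grid`` and one ``q<tau>`` column per
    quantile.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 30:
        raise ValueError(f"quantile LOESS needs at least 30 points, got {n}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    qs = sorted(quantiles)
    if any(not 0 < t < 1 for t in qs):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    kwin = max(int(np.ceil(span * n)), 2)
    curves = np.full((len(grid), len(qs)), np.nan)
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")[:kwin]
        h = d[order].max()
        if h == 0:
            w = np.ones(len(order))
        else:
            w = (1.0 - (d[order] / h) ** 3) ** 3
        use = w > 0
        if use.sum() < min_points:
            continue
        dxw = x[order][use] - x0
        yw = y[order][use]
        ww = w[use]
        for qi, tau in enumerate(qs):
            curves[gi, qi] = _local_quantile_fit(dxw, yw, ww, tau)
    curves = np.sort(curves, axis=1)  # enforce non-crossing
    out = pd.DataFrame({"grid": grid})
    for qi, tau in enumerate(qs):
        out[f"q{int(round(100 * tau))}"] = curves[:, qi]
    return out
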