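"""Shared statistical kernel.

Small, self-contained fitting routines used across the analysis modules:

* ordinary least squares on an explicit design matrix (QR based),
* two-way fixed-effects ANOVA with Type-II sums of squares,
* a random-intercept linear mixed model fitted by profile REML,
* Wilson score intervals for binomial fractions,
* a locally weighted (LOESS-style) polynomial smoother with extra
  multiplicative observation weights (used for biomass-weighted depth
  profiles).

Everything operates on plain numpy arrays and returns small dataclasses so
results serialize cleanly to CSV report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "LinearModelFit",
    "RandomInterceptFit",
    "ols",
    "design_from_factors",
    "two_way_anova",
    "tukey_hsd",
    "reml_random_intercept",
    "wilson_interval",
    "loess",
]


# ---------------------------------------------------------------------------
# ordinary least squares
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    """Result of an ordinary least-squares fit.

    ``coef`` are estimates for the columns of the design matrix, in order;
    ``cov`` is the coefficient covariance (sigma2 * (X'X)^-1).
    """

    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    df_resid: int
    sigma2: float
    rss: float
    names: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def t_test(self, index: int) -> tuple[float, float]:
        """t statistic and two-sided p-value for a single coefficient."""
        t = self.coef[index] / self.se[index]
        p = 2.0 * sps.t.sf(abs(t), self.df_resid)
        return float(t), float(p)

    def conf_int(self, index: int, level: float = 0.95) -> tuple[float, float]:
        q = sps.t.ppf(0.5 + level / 2.0, self.df_resid)
        return (
            float(self.coef[index] - q * self.se[index]),
            float(self.coef[index] + q * self.se[index]),
        )


def ols(y, X, names: list[str] | None = None) -> LinearModelFit:
    """Least squares via QR decomposition of the design matrix.

    Raises ``ValueError`` naming the offending columns if the design is rank
    deficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and design matrix have different lengths")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = max(diag.max(), 1.0)
    bad = np.where(diag < 1e-10 * scale)[0]
    if bad.size:
        cols = ", ".join(names[j] for j in bad)
        raise ValueError(f"design matrix is rank deficient (columns: {cols})")
    if n <= p:
        raise ValueError("need more observations than parameters")

    coef = np.linalg.solve(R, Q.T @ y)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    return LinearModelFit(
        coef=coef, se=se, cov=cov, df_resid=df, sigma2=sigma2, rss=rss,
        names=list(names), fitted=fitted, residuals=resid,
    )


def design_from_factors(*factors, intercept: bool = True):
    """Treatment-coded design matrix from categorical label arrays.

    Returns ``(X, names)``. The first level (sorted order) of each factor is
    the reference; one indicator column per remaining level.
    """
    n = len(np.asarray(factors[0][1], dtype=object))
    cols = [np.ones(n)] if intercept else []
    names = ["intercept"] if intercept else []
    for fname, labels in factors:
        labels = np.asarray(labels)
        levels = np.unique(labels)
        for lv in levels[1:]:
            cols.append((labels == lv).astype(float))
            names.append(f"{fname}[{lv}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# two-way ANOVA (Type-II sums of squares)
# ---------------------------------------------------------------------------

def _rss(y, X):
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    r = y - fitted
    return float(r @ r), int(rank)


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Additive two-way fixed-effects ANOVA, Type-II sums of squares.

    SS for each factor is the residual-sum-of-squares drop when adding that
    factor to a model already containing the other; F uses the residual mean
    square of the additive model. If a factor has a single level the analysis
    degrades to one-way for the other factor (the dropped factor gets NaN).

    Returns a DataFrame with rows per factor plus a residual row.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")

    la, lb = np.unique(a), np.unique(b)
    factors = []
    if la.size >= 2:
        factors.append((names[0], a))
    if lb.size >= 2:
        factors.append((names[1], b))
    if not factors:
        raise ValueError("both factors are constant; ANOVA is degenerate")

    X_full, _ = design_from_factors(*factors)
    rss_full, rank_full = _rss(y, X_full)
    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid
    # degeneracy scale: sums of squares below float noise relative to the
    # total variation are treated as exactly zero
    tss = float(((y - y.mean()) ** 2).sum())
    tol = 1e-12 * max(tss, 1.0)

    rows = []
    for fname, labels in (
        (names[0], a if la.size >= 2 else None),
        (names[1], b if lb.size >= 2 else None),
    ):
        if labels is None:
            rows.append({"factor": fname, "df": np.nan, "sum_sq": np.nan,
                         "F": np.nan, "p": np.nan})
            continue
        others = [f for f in factors if f[0] != fname]
        if others:
            X_red, _ = design_from_factors(*others)
        else:
            X_red = np.ones((len(y), 1))
        rss_red, rank_red = _rss(y, X_red)
        ss = max(rss_red - rss_full, 0.0)
        df = rank_full - rank_red
        if df <= 0:
            rows.append({"factor": fname, "df": 0, "sum_sq": 0.0,
                         "F": np.nan, "p": np.nan})
            continue
        if ms_resid <= tol:
            # zero residual variation: factor either explains nothing
            # (F = 0) or everything (F = inf)
            f_stat, p = (0.0, 1.0) if ss <= tol else (np.inf, 0.0)
        elif ss <= tol:
            f_stat, p = 0.0, 1.0
        else:
            f_stat = (ss / df) / ms_resid
            p = float(sps.f.sf(f_stat, df, df_resid))
        rows.append({"factor": fname, "df": df, "sum_sq": ss,
                     "F": f_stat, "p": p})
    rows.append({"factor": "residual", "df": df_resid, "sum_sq": rss_full,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def tukey_hsd(values, labels, alpha: float = 0.05):
    """Tukey HSD pairwise comparisons (post-hoc path), via statsmodels."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    return pairwise_tukeyhsd(np.asarray(values, dtype=float),
                             np.asarray(labels), alpha=alpha)


# ---------------------------------------------------------------------------
# random-intercept mixed model by profile REML
# ---------------------------------------------------------------------------

@dataclass
class RandomInterceptFit:
    """Random-intercept linear mixed model fit.

    Fixed effects estimated by GLS at the REML optimum of the variance ratio
    lambda = sigma_b^2 / sigma_e^2. ``p`` values use a normal approximation
    on estimate/SE (documented choice; no Satterthwaite correction).
    """

    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma_b2: float
    sigma_e2: float
    n_groups: int
    n_obs: int
    names: list[str] = field(default_factory=list)
    converged: bool = True
    method: str = "reml"

    def z_test(self, index: int) -> tuple[float, float]:
        z = self.coef[index] / self.se[index]
        return float(z), float(2.0 * sps.norm.sf(abs(z)))

    def conf_int(self, index: int, level: float = 0.95) -> tuple[float, float]:
        q = sps.norm.ppf(0.5 + level / 2.0)
        return (
            float(self.coef[index] - q * self.se[index]),
            float(self.coef[index] + q * self.se[index]),
        )


def _reml_pieces(lam, parts, n, p):
    """Profile-REML criterion pieces at variance ratio ``lam``.

    Uses the Woodbury identity per group:
    (I + lam J)^-1 = I - (lam / (1 + lam n_i)) J.
    Returns (criterion, beta, A, rss) where A = X' V^-1 X.
    """
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    quad = 0.0
    logdetV = 0.0
    for xtx, xt1, xty, sumy, yty, ni in parts:
        c = lam / (1.0 + lam * ni)
        A += xtx - c * np.outer(xt1, xt1)
        bvec += xty - c * xt1 * sumy
        quad += yty - c * sumy * sumy
        logdetV += math.log1p(lam * ni)
    beta = np.linalg.solve(A, bvec)
    rss = max(quad - beta @ bvec, 1e-300)
    sign, logdetA = np.linalg.slogdet(A)
    crit = (n - p) * math.log(rss) + logdetV + logdetA
    return crit, beta, A, rss


def reml_random_intercept(y, X, groups,
                          names: list[str] | None = None) -> RandomInterceptFit:
    """Random-intercept model y = X beta + b_group + e, fitted by REML.

    The REML objective is profiled down to the single variance ratio
    lambda = sigma_b^2/sigma_e^2 and optimized in one dimension; the boundary
    lambda = 0 (no between-group variance) collapses to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    k = uniq.size
    if k < 2:
        fit = ols(y, X, names)
        return RandomInterceptFit(
            coef=fit.coef, se=fit.se, cov=fit.cov, sigma_b2=0.0,
            sigma_e2=fit.sigma2, n_groups=k, n_obs=n, names=list(names),
            converged=True, method="ols_fallback",
        )

    parts = []
    for g in range(k):
        idx = inv == g
        Xg, yg = X[idx], y[idx]
        ones = np.ones(int(idx.sum()))
        parts.append((Xg.T @ Xg, Xg.T @ ones, Xg.T @ yg,
                      float(yg.sum()), float(yg @ yg), int(idx.sum())))

    def crit_at(t):
        return _reml_pieces(math.exp(t), parts, n, p)[0]

    res = optimize.minimize_scalar(crit_at, bounds=(-15.0, 15.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    crit0 = _reml_pieces(0.0, parts, n, p)[0]
    if res.fun < crit0 - 1e-10:
        lam = math.exp(res.x)
    else:
        lam = 0.0
    _, beta, A, rss = _reml_pieces(lam, parts, n, p)
    sigma_e2 = rss / (n - p)
    sigma_b2 = lam * sigma_e2
    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    return RandomInterceptFit(
        coef=beta, se=se, cov=cov, sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2), n_groups=k, n_obs=n, names=list(names),
        converged=bool(getattr(res, "success", True)),
    )


def reml_criterion(y, X, groups, lam: float) -> float:
    """REML criterion (up to a constant; smaller is better) at a given
    variance ratio — exposed for grid-based verification."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    parts = []
    for g in range(uniq.size):
        idx = inv == g
        Xg, yg = X[idx], y[idx]
        ones = np.ones(int(idx.sum()))
        parts.append((Xg.T @ Xg, Xg.T @ ones, Xg.T @ yg,
                      float(yg.sum()), float(yg @ yg), int(idx.sum())))
    return _reml_pieces(lam, parts, n, p)[0]


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    z = sps.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(center - half, 0.0)
    hi = 1.0 if k == n else min(center + half, 1.0)
    return (lo, hi)


# ---------------------------------------------------------------------------
# locally weighted polynomial smoother
# ---------------------------------------------------------------------------

def loess(x, y, *, weights=None, span: float = 0.75, degree: int = 2,
          xout=None) -> np.ndarray:
    """Locally weighted polynomial regression with a tricube kernel.

    At each evaluation point the nearest ``ceil(span * n)`` observations get
    tricube weights by scaled distance, multiplied by the optional
    observation ``weights`` (e.g. biomass). Observations with zero weight are
    dropped entirely so they influence neither the fit nor the bandwidth.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = (w > 0) & np.isfinite(y) & np.isfinite(x)
    x, y, w = x[keep], y[keep], w[keep]
    n = x.size
    if n < max(3, degree + 1):
        raise ValueError("too few points with positive weight for loess")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if xout is None:
        xout = x
    xout = np.atleast_1d(np.asarray(xout, dtype=float))

    r = int(np.ceil(span * n))
    r = max(r, degree + 1)
    r = min(r, n)

    fitted = np.empty(xout.size)
    for i, x0 in enumerate(xout):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")
        h = d[order[r - 1]]
        if h <= 0:
            # >= r observations exactly at x0: weighted mean of those
            at = d == 0
            fitted[i] = float(np.average(y[at], weights=w[at]))
            continue
        u = d / h
        tri = np.clip(1.0 - u ** 3, 0.0, None) ** 3
        comb = tri * w
        # guard against a degenerate local design (ties at the bandwidth)
        deg = degree
        while np.count_nonzero(comb) <= deg and deg > 0:
            deg -= 1
        if np.count_nonzero(comb) == 0:
            comb = w * (d <= h)
            deg = 0
        B = np.vander(x - x0, deg + 1, increasing=True)
        sw = np.sqrt(comb)
        beta, *_ = np.linalg.lstsq(sw[:, None] * B, sw * y, rcond=None)
        fitted[i] = beta[0]
    return fitted
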