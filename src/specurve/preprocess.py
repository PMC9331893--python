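"""Survey data preparation.

Order of operations in the standard pipeline: Little's MCAR test
(diagnostic only) -> multivariate-normal EM imputation -> scale scoring ->
standardization.  Imputed Likert values are deliberately left continuous:
the downstream analysis is linear regression on standardized variables and
rounding back to {1..4} would only add noise.  All sample variances use the
n-1 denominator; the EM estimates of (mu, Sigma) are maximum likelihood
(denominator n), as the likelihood requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import OUTCOME_COLUMNS, SCALE_COLUMNS

__all__ = [
    "MCARResult",
    "EMSettings",
    "EMImputer",
    "littles_mcar_test",
    "em_impute",
    "score_scales",
    "cronbach_alpha",
    "standardize",
]

logger = logging.getLogger(__name__)


@dataclass
class MCARResult:
    """Little's missing-completely-at-random test.

    chi2 is the pattern-wise Mahalanobis statistic
    d^2 = sum_j n_j (ybar_obs,j - mu_j)' Sigma_j^-1 (ybar_obs,j - mu_j)
    with (mu, Sigma) the EM estimates and j ranging over distinct
    missingness patterns; df = sum_j p_j - p.
    """

    chi2: float
    df: int
    p_value: float
    n_patterns: int
    n_used: int = 0
    n_dropped_all_missing: int = 0
    used_pinv: bool = False

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "n_patterns": self.n_patterns,
            "n_used": self.n_used,
            "n_dropped_all_missing": self.n_dropped_all_missing,
            "used_pinv": self.used_pinv,
        }


@dataclass
class EMSettings:
    """Convergence control for the multivariate-normal EM."""

    tol: float = 1e-5
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


# ---------------------------------------------------------------------------
# multivariate-normal EM core


def _pattern_groups(mask: np.ndarray):
    """Group row indices by missingness pattern (True = missing)."""
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    return [(patterns[g], np.flatnonzero(inverse == g)) for g in range(len(patterns))]


def _em_mvnorm(
    x: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """EM estimates of (mu, Sigma) for i.i.d. MVN rows with missing entries.

    Returns (mu, Sigma, log-likelihood path, converged).  The observed-data
    log-likelihood is asserted non-decreasing at every iteration (up to
    floating-point slack).
    """
    n, p = x.shape
    mask = np.isnan(x)
    if np.any(mask.all(axis=0)):
        bad = np.flatnonzero(mask.all(axis=0))
        raise ValueError(f"variable(s) entirely missing at positions {bad.tolist()}")
    groups = _pattern_groups(mask)

    mu = np.nanmean(x, axis=0)
    var = np.nanvar(x, axis=0)
    var = np.where(var <= 0, 1.0, var)
    sigma = np.diag(var)

    ll_path: list[float] = []
    converged = False
    for _ in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        ll = 0.0
        for pat, idx in groups:
            obs = ~pat
            xo = x[np.ix_(idx, obs)]
            k = len(idx)
            po = int(obs.sum())
            if po == 0:
                continue
            s_oo = sigma[np.ix_(obs, obs)]
            dev = xo - mu[obs]
            try:
                chol = np.linalg.cholesky(s_oo)
                sol = np.linalg.solve(chol, dev.T)
                quad = np.sum(sol**2)
                logdet = 2 * np.sum(np.log(np.diag(chol)))
                s_oo_inv_dev = np.linalg.solve(chol.T, sol).T
            except np.linalg.LinAlgError:
                s_oo_inv = np.linalg.pinv(s_oo)
                s_oo_inv_dev = dev @ s_oo_inv
                quad = float(np.sum(dev * s_oo_inv_dev))
                sign, logdet = np.linalg.slogdet(s_oo)
                logdet = logdet if sign > 0 else 0.0
            ll += -0.5 * (k * (po * np.log(2 * np.pi) + logdet) + quad)

            filled = np.empty((k, p))
            filled[:, obs] = xo
            if pat.any():
                mis = pat
                s_mo = sigma[np.ix_(mis, obs)]
                cond_mean = mu[mis] + s_oo_inv_dev @ s_mo.T
                filled[:, mis] = cond_mean
                # conditional covariance of the missing block
                try:
                    c = s_mo @ np.linalg.solve(s_oo, s_mo.T)
                except np.linalg.LinAlgError:
                    c = s_mo @ np.linalg.pinv(s_oo) @ s_mo.T
                cond_cov = sigma[np.ix_(mis, mis)] - c
                t2[np.ix_(mis, mis)] += k * cond_cov
            t1 += filled.sum(axis=0)
            t2 += filled.T @ filled

        mu_new = t1 / n
        sigma_new = t2 / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)

        if ll_path:
            slack = 1e-6 * (1 + abs(ll_path[-1]))
            assert ll >= ll_path[-1] - slack, (
                f"EM log-likelihood decreased: {ll_path[-1]} -> {ll}"
            )
        ll_path.append(ll)
        mu, sigma = mu_new, sigma_new
        if len(ll_path) >= 2 and ll_path[-1] - ll_path[-2] < tol:
            converged = True
            break
        if not np.isnan(x).any():
            converged = True
            break
    return mu, sigma, ll_path, converged


class EMImputer(TransformerMixin, BaseEstimator):
    """Single imputation under a multivariate normal model.

    ``fit`` runs EM to the maximum-likelihood (mu, Sigma); ``transform``
    replaces each missing cell by its conditional mean given the row's
    observed cells at the fitted parameters.  Observed cells are never
    altered.

    Parameters
    ----------
    tol : float
        Stop when the observed-data log-likelihood improves by less.
    max_iter : int
        Iteration cap; non-convergence is logged, not raised.
    """

    def __init__(self, tol: float = 1e-5, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        settings = EMSettings(tol=self.tol, max_iter=self.max_iter)
        mu, sigma, ll_path, converged = _em_mvnorm(
            x, settings.tol, settings.max_iter
        )
        self.mean_ = mu
        self.covariance_ = sigma
        self.loglik_path_ = np.asarray(ll_path)
        self.n_iter_ = len(ll_path)
        self.converged_ = converged
        self.n_features_in_ = x.shape[1]
        if not converged:
            logger.warning("EM did not converge in %d iterations", self.max_iter)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        x = np.asarray(X, dtype=float).copy()
        mask = np.isnan(x)
        mu, sigma = self.mean_, self.covariance_
        for pat, idx in _pattern_groups(mask):
            if not pat.any():
                continue
            obs = ~pat
            mis = pat
            if obs.any():
                s_oo = sigma[np.ix_(obs, obs)]
                s_mo = sigma[np.ix_(mis, obs)]
                dev = x[np.ix_(idx, obs)] - mu[obs]
                try:
                    x[np.ix_(idx, mis)] = mu[mis] + np.linalg.solve(s_oo, dev.T).T @ s_mo.T
                except np.linalg.LinAlgError:
                    x[np.ix_(idx, mis)] = mu[mis] + dev @ np.linalg.pinv(s_oo) @ s_mo.T
            else:
                x[np.ix_(idx, mis)] = mu[mis]
        return x


def em_impute(
    data: pd.DataFrame,
    variables: list[str] | None = None,
    settings: EMSettings | None = None,
) -> pd.DataFrame:
    """EM-impute the given columns of a survey table (all columns with any
    missing value, minus identifiers, by default).  Returns a copy with
    missing cells replaced by conditional means; imputed Likert values stay
    continuous."""
    settings = settings or EMSettings()
    if variables is None:
        variables = [
            c
            for c in data.columns
            if c not in ("participant_id", "owns_smartphone")
            and pd.api.types.is_numeric_dtype(data[c])
        ]
    block = data[variables].astype(float)
    fully_missing = [c for c in variables if block[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variable(s) entirely missing: {fully_missing}")
    out = data.copy()
    if not block.isna().any().any():
        return out
    imputer = EMImputer(tol=settings.tol, max_iter=settings.max_iter)
    out[variables] = imputer.fit(block.to_numpy()).transform(block.to_numpy())
    out.attrs["em_converged"] = imputer.converged_
    out.attrs["em_n_iter"] = imputer.n_iter_
    return out


# ---------------------------------------------------------------------------
# Little's MCAR test


def littles_mcar_test(data: pd.DataFrame, variables: list[str]) -> MCARResult:
    """Little's chi-square test of the MCAR hypothesis.

    Compares each missingness pattern's observed-variable means with the EM
    estimates; under MCAR the summed Mahalanobis distance is chi-square with
    sum_j p_j - p degrees of freedom.  Rows missing every variable are
    dropped (with a logged count); a singular pattern covariance falls back
    to the pseudo-inverse and sets ``used_pinv``.
    """
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    x = data[variables].astype(float).to_numpy()
    mask = np.isnan(x)
    all_missing = mask.all(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        logger.info("Little's test: dropping %d all-missing rows", n_dropped)
        x = x[~all_missing]
        mask = mask[~all_missing]
    n, p = x.shape

    if not mask.any():
        return MCARResult(0.0, 0, 1.0, 1, n_used=n, n_dropped_all_missing=n_dropped)

    mu, sigma, _, _ = _em_mvnorm(x, tol=1e-6, max_iter=500)
    groups = _pattern_groups(mask)
    chi2 = 0.0
    df = 0
    used_pinv = False
    for pat, idx in groups:
        obs = ~pat
        po = int(obs.sum())
        if po == 0:
            continue
        ybar = x[np.ix_(idx, obs)].mean(axis=0)
        dev = ybar - mu[obs]
        s_oo = sigma[np.ix_(obs, obs)]
        try:
            sol = np.linalg.solve(s_oo, dev)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(s_oo) @ dev
            used_pinv = True
        chi2 += len(idx) * float(dev @ sol)
        df += po
    df -= p
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return MCARResult(
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        n_patterns=len(groups),
        n_used=n,
        n_dropped_all_missing=n_dropped,
        used_pinv=used_pinv,
    )


# ---------------------------------------------------------------------------
# scoring, reliability, standardization


def score_scales(data: pd.DataFrame) -> pd.DataFrame:
    """Add the three relationship totals: parent-child = sum of 11 items,
    peer = sum of 10, teacher-student = sum of 5.  Higher totals mean a
    better relationship.  Requires complete (imputed) scale items."""
    out = data.copy()
    for outcome in OUTCOME_COLUMNS:
        cols = SCALE_COLUMNS[outcome]
        missing_cols = [c for c in cols if c not in data.columns]
        if missing_cols:
            raise ValueError(f"missing scale item columns: {missing_cols}")
        block = data[cols]
        if block.isna().any().any():
            raise ValueError(
                f"scale items for {outcome!r} contain missing values; impute first"
            )
        out[outcome] = block.sum(axis=1)
    return out


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(var_i)/var(total)), ddof=1."""
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D table with >= 2 rows and >= 2 items")
    if np.isnan(arr).any():
        raise ValueError("items contain missing values")
    k = arr.shape[1]
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def standardize(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Transform each column to sample mean 0 and sample SD 1 (ddof=1)."""
    out = data.copy()
    for col in columns:
        vals = data[col].astype(float)
        if vals.isna().any():
            raise ValueError(f"column {col!r} contains missing values")
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (vals - vals.mean()) / sd
    return out
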