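"""Specification-curve estimation.

A *specification* is one complete analytic choice: an outcome (one of the
three relationship totals), a predictor (one of the 20 content items), and
a set of control variables.  The default design crosses 20 predictors x 3
outcomes x 7 covariate sets = 420 specifications; each is a standardized
OLS regression, and the curve is the sorted collection of the predictor
coefficients with per-predictor summaries (median beta, sign/significance
counts, NSRPD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import CONTENT_COLUMNS, COVARIATE_COLUMNS, OUTCOME_COLUMNS

__all__ = [
    "Specification",
    "SpecResult",
    "CurveSummary",
    "SpecificationCurve",
    "build_covariate_sets",
    "enumerate_specifications",
    "fit_specification",
    "run_curve",
    "summarize_curve",
    "results_to_frame",
]


@dataclass(frozen=True)
class Specification:
    """One (outcome, predictor, covariate-set) triple."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} cannot be a covariate")
        if self.outcome in self.covariates or self.outcome == self.predictor:
            raise ValueError(f"outcome {self.outcome!r} cannot be a regressor")

    def label(self) -> str:
        covs = "+".join(self.covariates) if self.covariates else "none"
        return f"{self.outcome}~{self.predictor}|{covs}"


@dataclass
class SpecResult:
    """Standardized OLS estimate for one specification.

    ``beta`` is the predictor's coefficient in a regression of the
    standardized outcome on the standardized predictor and covariates
    (intercept included); ``partial_r2 = t^2 / (t^2 + df)``.
    """

    spec: Specification
    n: int
    beta: float
    se: float
    t: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    partial_r2: float


@dataclass
class CurveSummary:
    """Per-predictor curve descriptives.

    NSRPD = number of specifications individually significant (p < alpha)
    with the sign of the median effect (the predominant direction).
    """

    predictor: str
    median_beta: float
    n_specs: int
    n_sig_pos: int
    n_sig_neg: int
    n_nonsig: int
    dominant_sign: str
    nsrpd: int
    alpha: float
    median_spec: Specification | None = field(default=None, repr=False)
    partial_r2_at_median: float = float("nan")
    median_partial_r2: float = float("nan")


# ---------------------------------------------------------------------------
# design enumeration


def build_covariate_sets(covariates: list[str]) -> list[tuple[str, ...]]:
    """Default covariate lattice: no controls, each single control, all
    controls — 7 sets for the five study covariates."""
    if len(set(covariates)) != len(covariates):
        raise ValueError("duplicate covariate names")
    sets: list[tuple[str, ...]] = [()]
    sets += [(c,) for c in covariates]
    full = tuple(covariates)
    if full not in sets:
        sets.append(full)
    # dedup preserving order (degenerate for 0 or 1 covariate)
    seen: set[tuple[str, ...]] = set()
    out = []
    for s in sets:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def enumerate_specifications(
    predictors: list[str],
    outcomes: list[str],
    covariate_sets: list[tuple[str, ...]],
) -> list[Specification]:
    """Full cross of outcomes x predictors x covariate sets, outcome-major
    deterministic order."""
    if not predictors or not outcomes or not covariate_sets:
        raise ValueError("predictors, outcomes and covariate_sets must be non-empty")
    specs = [
        Specification(outcome=o, predictor=x, covariates=tuple(c))
        for o in outcomes
        for x in predictors
        for c in covariate_sets
    ]
    if len(set(specs)) != len(specs):
        raise ValueError("duplicate specifications in design")
    return specs


# ---------------------------------------------------------------------------
# estimation


def _ols(x: np.ndarray, y: np.ndarray):
    """OLS via QR; returns (coef, XtX_inv, rss, rank check raises)."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        raise np.linalg.LinAlgError("rank deficient")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - x @ coef
    rss = float(resid @ resid)
    r_inv = np.linalg.solve(r, np.eye(r.shape[0]))
    xtx_inv = r_inv @ r_inv.T
    return coef, xtx_inv, rss


def fit_specification(data: pd.DataFrame, spec: Specification) -> SpecResult:
    """Fit one standardized OLS specification.

    Expects the outcome, predictor and covariates to be standardized
    columns of ``data``.  Returns the predictor's coefficient with its
    standard error, t, two-sided p (t distribution), 95% CI and partial r^2.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    frame = data[cols]
    if frame.isna().any().any():
        raise ValueError(f"missing values in specification {spec.label()}; impute first")
    y = frame[spec.outcome].to_numpy(dtype=float)
    n = len(y)
    k = 1 + len(spec.covariates)
    if n <= k + 1:
        raise ValueError(f"insufficient rows (n={n}) for {k} regressors")
    x = np.column_stack(
        [np.ones(n), frame[spec.predictor].to_numpy(dtype=float)]
        + [frame[c].to_numpy(dtype=float) for c in spec.covariates]
    )
    for j, name in enumerate([spec.predictor, *spec.covariates], start=1):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"regressor {name!r} is constant")
    try:
        coef, xtx_inv, rss = _ols(x, y)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"collinear regressors in specification {spec.label()}"
        ) from None
    df = n - x.shape[1]
    sigma2 = rss / df
    beta = float(coef[1])
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    if se > 0:
        t = beta / se
        partial_r2 = t**2 / (t**2 + df)
    else:  # exact fit: zero residual variance
        t = np.inf * np.sign(beta) if beta != 0 else 0.0
        partial_r2 = 1.0 if beta != 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return SpecResult(
        spec=spec,
        n=n,
        beta=beta,
        se=se,
        t=t,
        df=df,
        p_value=p,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        partial_r2=float(partial_r2),
    )


def run_curve(data: pd.DataFrame, specs: list[Specification]) -> list[SpecResult]:
    """Fit every specification; result order matches ``specs``."""
    if not specs:
        raise ValueError("specs must be non-empty")
    results = []
    for spec in specs:
        try:
            results.append(fit_specification(data, spec))
        except ValueError as err:
            raise ValueError(f"specification {spec.label()} failed: {err}") from err
    return results


def sort_results(results: list[SpecResult]) -> list[SpecResult]:
    """Ascending by beta; ties broken by original order (stable sort)."""
    return sorted(results, key=lambda r: r.beta)


def summarize_curve(results: list[SpecResult], alpha: float = 0.05) -> CurveSummary:
    """Per-predictor curve summary: median beta (mean of middle two for
    even counts), sign/significance counts and NSRPD at level ``alpha``.
    A dominant-sign tie at median 0 goes to the side with more significant
    results."""
    if not results:
        raise ValueError("results must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    predictors = {r.spec.predictor for r in results}
    if len(predictors) != 1:
        raise ValueError(f"mixed predictors in summary: {sorted(predictors)}")
    predictor = predictors.pop()

    betas = np.array([r.beta for r in results])
    pvals = np.array([r.p_value for r in results])
    sig = pvals < alpha
    n_sig_pos = int(np.sum(sig & (betas > 0)))
    n_sig_neg = int(np.sum(sig & (betas < 0)))
    n_nonsig = len(results) - n_sig_pos - n_sig_neg
    median_beta = float(np.median(betas))
    if median_beta > 0:
        dominant = "+"
    elif median_beta < 0:
        dominant = "-"
    else:
        dominant = "+" if n_sig_pos >= n_sig_neg else "-"
    nsrpd = n_sig_pos if dominant == "+" else n_sig_neg

    # the specification whose beta sits at (or nearest) the median
    order = np.argsort(betas, kind="stable")
    mid = order[(len(results) - 1) // 2]
    median_spec_result = results[int(mid)]

    return CurveSummary(
        predictor=predictor,
        median_beta=median_beta,
        n_specs=len(results),
        n_sig_pos=n_sig_pos,
        n_sig_neg=n_sig_neg,
        n_nonsig=n_nonsig,
        dominant_sign=dominant,
        nsrpd=int(nsrpd),
        alpha=alpha,
        median_spec=median_spec_result.spec,
        partial_r2_at_median=float(median_spec_result.partial_r2),
        median_partial_r2=float(np.median([r.partial_r2 for r in results])),
    )


def results_to_frame(results: list[SpecResult]) -> pd.DataFrame:
    """One row per specification, covariates joined by '+'."""
    return pd.DataFrame(
        {
            "outcome": [r.spec.outcome for r in results],
            "predictor": [r.spec.predictor for r in results],
            "covariates": ["+".join(r.spec.covariates) for r in results],
            "n": [r.n for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "partial_r2": [r.partial_r2 for r in results],
        }
    )


# ---------------------------------------------------------------------------
# estimator surface


class SpecificationCurve(BaseEstimator):
    """Multiverse of standardized OLS regressions.

    Parameters
    ----------
    outcomes, predictors : lists of column names; default the three
        relationship totals and the 20 content items.
    covariates : list of candidate controls; expanded to the default
        lattice (none / each singleton / all) unless ``covariate_sets``
        gives explicit sets.
    alpha : significance level for the per-predictor summaries.

    Attributes
    ----------
    specs_ : list of Specification, outcome-major order.
    results_ : list of SpecResult aligned with ``specs_``.
    summaries_ : dict predictor -> CurveSummary.
    """

    def __init__(
        self,
        outcomes: list[str] | None = None,
        predictors: list[str] | None = None,
        covariates: list[str] | None = None,
        covariate_sets: list[tuple[str, ...]] | None = None,
        alpha: float = 0.05,
    ):
        self.outcomes = outcomes
        self.predictors = predictors
        self.covariates = covariates
        self.covariate_sets = covariate_sets
        self.alpha = alpha

    def _design(self):
        outcomes = self.outcomes or OUTCOME_COLUMNS
        predictors = self.predictors or CONTENT_COLUMNS
        if self.covariate_sets is not None:
            cov_sets = [tuple(s) for s in self.covariate_sets]
        else:
            cov_sets = build_covariate_sets(
                self.covariates if self.covariates is not None else COVARIATE_COLUMNS
            )
        return outcomes, predictors, cov_sets

    def fit(self, X: pd.DataFrame, y=None):
        outcomes, predictors, cov_sets = self._design()
        self.specs_ = enumerate_specifications(predictors, outcomes, cov_sets)
        self.results_ = run_curve(X, self.specs_)
        self.summaries_ = {
            p: summarize_curve(
                [r for r in self.results_ if r.spec.predictor == p], self.alpha
            )
            for p in predictors
        }
        return self

    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results_)

    def curve_frame(self) -> pd.DataFrame:
        """Results sorted ascending by beta with an x-index for plotting."""
        frame = results_to_frame(sort_results(self.results_))
        frame.insert(0, "x_index", np.arange(1, len(frame) + 1))
        return frame
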