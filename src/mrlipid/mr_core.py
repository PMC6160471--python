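"""Causal-effect estimators for two-sample summary-statistic MR.

Given J harmonized instruments with exposure effects ``beta_X[j]`` (per SD,
standard error ``se_X[j]``) and outcome effects ``beta_Y[j]`` (log-odds,
standard error ``se_Y[j]``), each estimator returns the causal log-odds of
the outcome per SD increment in the exposure:

* ``wald_ratio`` — single-variant ratio beta_Y / beta_X with first- and
  second-order delta-method standard errors;
* ``ivw``        — inverse-variance-weighted meta-analysis, equivalent to a
  zero-intercept weighted regression of beta_Y on beta_X with weights
  1/se_Y²; under the multiplicative random-effects model the standard error
  is inflated by phi = max(1, sqrt(Q/(J-1))) where Q is Cochran's statistic;
* ``egger``      — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and its test is the Egger
  intercept test;
* ``weighted_median`` — the 50% point of the inverse-variance-weighted
  empirical distribution of per-variant ratios, consistent as long as valid
  instruments carry at least half the weight; CI by parametric bootstrap;
* ``ivw_correlated`` / ``egger_correlated`` — generalized-least-squares
  versions for cis instruments in linkage disequilibrium, with outcome
  covariance Omega[j,k] = se_Y[j] se_Y[k] rho[j,k].

All confidence intervals use the normal 95% quantile for consistency across
variant counts.  Estimates exponentiate to the odds-ratio scale via
``to_odds_ratio``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .instruments import LDMatrix

__all__ = [
    "MREstimateError",
    "MREstimate",
    "RatioEstimate",
    "extract_arrays",
    "wald_ratio",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "ivw_correlated",
    "egger_correlated",
    "to_odds_ratio",
]

Z95 = stats.norm.ppf(0.975)  # 1.959964...
RIDGE_FRACTION = 1e-10


class MREstimateError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass
class MREstimate:
    """A causal estimate on the log-odds-per-SD scale.

    ``scale_factor`` is the multiplicative variance-inflation phi applied to
    the base standard error (1.0 under fixed effects or when the residual
    dispersion is below its expectation).  Egger fits also carry the
    intercept, its standard error and the intercept-test p-value.
    """

    method: str
    beta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.se_hat > 0:
            raise MREstimateError("standard error must be positive")
        if not (self.ci_low <= self.beta_hat <= self.ci_high):
            raise MREstimateError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RatioEstimate:
    """Single-variant ratio estimate with both delta-method error orders.

    se_first  = se_Y / |beta_X|
    se_second = sqrt(se_Y²/beta_X² + beta_Y²·se_X²/beta_X⁴)
    """

    rsid: str
    ratio: float
    se_first: float
    se_second: float


def extract_arrays(instruments: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Retained (flag ``none``) rows as (beta_X, se_X, beta_Y, se_Y, rsids)."""
    df = instruments
    if "exclusion_flag" in df.columns:
        df = df[df["exclusion_flag"] == "none"]
    if df.empty:
        raise MREstimateError("no retained instruments")
    return (
        df["beta_exposure"].to_numpy(float),
        df["se_exposure"].to_numpy(float),
        df["beta_outcome"].to_numpy(float),
        df["se_outcome"].to_numpy(float),
        df["rsid"].astype(str).to_list(),
    )


def _finish(method, beta, se, j, phi=1.0, intercept=None, intercept_se=None):
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    ip = None
    if intercept is not None and intercept_se is not None:
        ip = 2.0 * stats.norm.sf(abs(intercept) / intercept_se)
    return MREstimate(
        method=method,
        beta_hat=float(beta),
        se_hat=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(p),
        n_variants=int(j),
        intercept=None if intercept is None else float(intercept),
        intercept_se=None if intercept_se is None else float(intercept_se),
        intercept_p=None if ip is None else float(ip),
        scale_factor=float(phi),
    )


def wald_ratio(inst) -> RatioEstimate:
    """Ratio estimate for a single instrument (row of a harmonized table)."""
    bx, sx, by, sy = (
        float(inst["beta_exposure"]),
        float(inst["se_exposure"]),
        float(inst["beta_outcome"]),
        float(inst["se_outcome"]),
    )
    if bx == 0:
        raise MREstimateError(f"non-informative instrument {inst['rsid']}: beta_exposure = 0")
    ratio = by / bx
    se1 = sy / abs(bx)
    se2 = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return RatioEstimate(str(inst["rsid"]), ratio, float(se1), float(se2))


def ratio_estimates(instruments: pd.DataFrame) -> list[RatioEstimate]:
    """Per-variant ratio estimates for every retained instrument."""
    bx, sx, by, sy, rsids = extract_arrays(instruments)
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )
    return [wald_ratio(row) for _, row in df.iterrows()]


def ivw(
    instruments: pd.DataFrame,
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_Y on beta_X through the
    origin with weights 1/se_Y².  ``effects_model`` selects the standard
    error: ``fixed`` uses the meta-analytic error, ``multiplicative_random``
    (default) scales it by phi = max(1, sqrt(Q/(J-1))) with Q the
    first-order Cochran heterogeneity statistic at the estimate, so excess
    dispersion widens the interval but phi never shrinks below 1.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise MREstimateError(f"unknown effects model {effects_model!r}")
    bx, sx, by, sy, rsids = extract_arrays(instruments)
    j = len(bx)
    if np.all(sy == 0):
        raise MREstimateError("all outcome standard errors are zero")
    if j == 1:
        warnings.warn("single instrument: IVW degrades to the Wald ratio", stacklevel=2)
        r = wald_ratio(
            {
                "rsid": rsids[0],
                "beta_exposure": bx[0],
                "se_exposure": sx[0],
                "beta_outcome": by[0],
                "se_outcome": sy[0],
            }
        )
        return _finish("ivw", r.ratio, r.se_first, 1)
    w = sy**-2.0
    sxx = np.sum(bx**2 * w)
    if sxx == 0:
        raise MREstimateError("exposure effects all zero: unidentifiable")
    beta = np.sum(bx * by * w) / sxx
    se_fixed = sxx**-0.5
    q = np.sum(w * (by - beta * bx) ** 2)
    phi = max(1.0, np.sqrt(q / (j - 1))) if effects_model == "multiplicative_random" else 1.0
    return _finish("ivw", beta, se_fixed * phi, j, phi)


def egger(instruments: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: weighted least squares with a free intercept.

    Requires the exposure-increasing orientation produced by harmonization
    (the slope is not invariant to per-variant allele flips once an
    intercept is allowed).  Standard errors are scaled by
    phi = max(1, sqrt(RSS_w/(J-2))).  A small intercept p-value indicates
    directional pleiotropy.
    """
    bx, sx, by, sy, _ = extract_arrays(instruments)
    j = len(bx)
    if j < 3:
        raise MREstimateError("MR-Egger requires at least 3 variants")
    if np.any(bx < 0):
        raise MREstimateError(
            "negative exposure effects: orient instruments to the increasing allele first"
        )
    if np.var(bx) == 0:
        raise MREstimateError("zero variance in exposure effects: slope unidentifiable")
    w = sy**-2.0
    # weighted normal equations for (intercept, slope)
    X = np.column_stack([np.ones(j), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = linalg.solve(xtwx, XtW @ by, assume_a="pos")
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = linalg.inv(xtwx)
    se_a, se_b = np.sqrt(np.diag(cov)) * phi
    return _finish("egger", coef[1], se_b, j, phi, intercept=coef[0], intercept_se=se_a)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical ratio distribution.

    Ratios are sorted ascending; normalized weights w define cumulative
    midpoint positions s_j = cumsum(w)_j - w_j/2, and the estimate is the
    linear interpolation of the sorted ratios at s = 1/2.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Weights are inverse first-order ratio variances.  The bootstrap redraws
    beta_X*[j] ~ N(beta_X[j], se_X[j]²) and beta_Y*[j] ~ N(beta_Y[j],
    se_Y[j]²) and recomputes the weighted median ``n_boot`` times; the
    standard error is the standard deviation over replicates.  The
    estimator is consistent while invalid instruments carry < 50% of the
    total weight (breakdown property).
    """
    if seed is None:
        raise MREstimateError("weighted_median requires an explicit seed")
    if n_boot < 100:
        raise MREstimateError("n_boot must be at least 100")
    bx, sx, by, sy, _ = extract_arrays(instruments)
    j = len(bx)
    if j < 3:
        raise MREstimateError("weighted median requires at least 3 variants")
    if np.any(bx == 0):
        raise MREstimateError("beta_exposure = 0 gives an undefined ratio")
    ratios = by / bx
    weights = (np.abs(bx) / sy) ** 2  # 1 / first-order ratio variance
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx_star[b]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        boots[b] = _weighted_median_point(by_star[b] / bxs, (np.abs(bxs) / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return _finish("weighted_median", beta, se, j)


def _conditioned_omega(sy: np.ndarray, rho: np.ndarray) -> np.ndarray:
    omega = np.outer(sy, sy) * rho
    omega = omega + RIDGE_FRACTION * np.mean(np.diag(omega)) * np.eye(len(sy))
    return omega


def _gls_solve(X: np.ndarray, y: np.ndarray, omega: np.ndarray):
    """GLS coefficients and unscaled covariance via Cholesky factorization.

    Never forms the explicit inverse of Omega; the explicit-inverse path is
    kept as an independent oracle in the test suite.
    """
    try:
        cho = linalg.cho_factor(omega, lower=True)
    except linalg.LinAlgError as exc:
        raise MREstimateError(
            "outcome covariance not positive-definite; prune instruments more strongly"
        ) from exc
    oi_X = linalg.cho_solve(cho, X)
    oi_y = linalg.cho_solve(cho, y)
    xtox = X.T @ oi_X
    coef = linalg.solve(xtox, X.T @ oi_y, assume_a="pos")
    cov = linalg.inv(xtox)
    resid = y - X @ coef
    q = float(resid @ linalg.cho_solve(cho, resid))
    return coef, cov, q


def ivw_correlated(instruments: pd.DataFrame, ld: LDMatrix) -> MREstimate:
    """IVW for correlated instruments via generalized least squares.

    The outcome covariance is Omega[j,k] = se_Y[j] se_Y[k] rho[j,k] with
    rho the signed LD correlation; the estimate is the zero-intercept GLS
    slope (x' Omega^-1 y) / (x' Omega^-1 x), and the standard error
    (x' Omega^-1 x)^-1/2 scaled by phi = max(1, sqrt(q/(J-1))) with q the
    GLS residual quadratic form.  Reduces exactly to ``ivw`` at identity LD.
    """
    bx, sx, by, sy, rsids = extract_arrays(instruments)
    j = len(bx)
    if j < 2:
        raise MREstimateError("correlated IVW requires at least 2 variants")
    rho = ld.subset(rsids).values
    omega = _conditioned_omega(sy, rho)
    X = bx.reshape(-1, 1)
    coef, cov, q = _gls_solve(X, by, omega)
    phi = max(1.0, np.sqrt(q / (j - 1)))
    return _finish("ivw_correlated", coef[0], np.sqrt(cov[0, 0]) * phi, j, phi)


def egger_correlated(instruments: pd.DataFrame, ld: LDMatrix) -> MREstimate:
    """MR-Egger for correlated instruments (GLS with design (1, beta_X))."""
    bx, sx, by, sy, rsids = extract_arrays(instruments)
    j = len(bx)
    if j < 3:
        raise MREstimateError("correlated Egger requires at least 3 variants")
    if np.any(bx < 0):
        raise MREstimateError(
            "negative exposure effects: orient instruments to the increasing allele first"
        )
    rho = ld.subset(rsids).values
    omega = _conditioned_omega(sy, rho)
    X = np.column_stack([np.ones(j), bx])
    coef, cov, q = _gls_solve(X, by, omega)
    phi = max(1.0, np.sqrt(q / (j - 2)))
    se_a, se_b = np.sqrt(np.diag(cov)) * phi
    return _finish(
        "egger_correlated", coef[1], se_b, j, phi, intercept=coef[0], intercept_se=se_a
    )


def to_odds_ratio(est: MREstimate, decimals: int | None = None) -> dict:
    """Exponentiate an estimate to the odds-ratio scale.

    Rounding (``decimals``) is applied only at presentation; the returned
    p-value is untouched.
    """
    d = {
        "method": est.method,
        "odds_ratio": float(np.exp(est.beta_hat)),
        "ci_low": float(np.exp(est.ci_low)),
        "ci_high": float(np.exp(est.ci_high)),
        "pvalue": est.pvalue,
        "n_variants": est.n_variants,
    }
    if decimals is not None:
        for k in ("odds_ratio", "ci_low", "ci_high"):
            d[k] = round(d[k], decimals)
    return d
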