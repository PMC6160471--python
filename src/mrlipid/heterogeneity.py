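"""Heterogeneity and pleiotropy diagnostics: Q' and the MR-PRESSO workflow.

Dispersion of per-variant causal estimates beyond what their sampling errors
explain is the summary-statistic signature of horizontal pleiotropy.  Two
complementary diagnostics are provided:

* **Q'** — a Cochran-type statistic with modified second-order weights,
  Q(b) = sum_j (beta_Y[j] - b*beta_X[j])² / (se_Y[j]² + b²*se_X[j]²),
  minimized exactly over the causal effect b.  The denominator carries the
  exposure uncertainty, easing the no-measurement-error (NOME) assumption;
  the minimized value is referred to chi-square with J-1 degrees of freedom.

* **MR-PRESSO** — a resampling test that compares the observed residual sum
  of squares around leave-one-out IVW fits to its Monte-Carlo distribution
  under no pleiotropy (global test), flags individual variants whose
  residual is extreme against its simulated distribution (outlier test),
  and re-estimates after removal (remove-and-retest workflow).

Empirical p-values use the add-one correction (never exactly zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mr_core import MREstimate, MREstimateError, extract_arrays, ivw

__all__ = [
    "HeterogeneityReport",
    "PressoReport",
    "q_prime",
    "cochran_q",
    "presso_global",
    "presso_outliers",
    "presso_workflow",
]


@dataclass
class HeterogeneityReport:
    """Minimized Q' statistic with its chi-square reference."""

    q_prime: float
    df: int
    pvalue: float
    beta_at_min: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PressoReport:
    """Outcome of the MR-PRESSO global / outlier / retest workflow."""

    rss_observed: float
    global_p: float
    outlier_pvalues: dict = field(default_factory=dict)
    outliers: list = field(default_factory=list)
    adjusted: MREstimate | None = None
    post_removal: HeterogeneityReport | None = None
    n_sim: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "rss_observed": self.rss_observed,
            "global_p": self.global_p,
            "outlier_pvalues": self.outlier_pvalues,
            "outliers": self.outliers,
            "adjusted": self.adjusted.to_dict() if self.adjusted else None,
            "post_removal": self.post_removal.to_dict() if self.post_removal else None,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def cochran_q(instruments: pd.DataFrame, beta: float | None = None) -> float:
    """First-order Cochran Q at ``beta`` (IVW fixed-effect estimate if None)."""
    bx, sx, by, sy, _ = extract_arrays(instruments)
    if beta is None:
        beta = ivw(instruments, effects_model="fixed").beta_hat
    return float(np.sum((by - beta * bx) ** 2 / sy**2))


def q_prime(instruments: pd.DataFrame) -> HeterogeneityReport:
    """Exact Q' heterogeneity statistic with modified second-order weights.

    Minimizes Q(b) = sum_j (beta_Y[j] - b*beta_X[j])² / (se_Y[j]² +
    b²*se_X[j]²) by bounded one-dimensional search bracketing ±10x the IVW
    estimate (widened to a minimum half-width so a near-zero IVW estimate
    still yields a proper bracket), tolerance 1e-10.  The upper-tail
    chi-square p-value uses J-1 degrees of freedom.  In the limit se_X -> 0
    the statistic equals the first-order Cochran Q at the IVW estimate.
    """
    bx, sx, by, sy, _ = extract_arrays(instruments)
    j = len(bx)
    if j < 2:
        raise MREstimateError("Q' requires at least 2 variants")

    def q_of(b: float) -> float:
        return float(np.sum((by - b * bx) ** 2 / (sy**2 + b**2 * sx**2)))

    center = ivw(instruments, effects_model="fixed").beta_hat
    half = 10.0 * max(abs(center), 0.1)
    res = optimize.minimize_scalar(
        q_of,
        bounds=(center - half, center + half),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise MREstimateError(f"Q' minimization did not converge: {res.message}")
    q = max(0.0, float(res.fun))
    return HeterogeneityReport(
        q_prime=q,
        df=j - 1,
        pvalue=float(stats.chi2.sf(q, j - 1)),
        beta_at_min=float(res.x),
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes, one per variant.

    Works on batched inputs: the last axis indexes variants.
    """
    sxy = np.sum(bx * by * w, axis=-1, keepdims=True)
    sxx = np.sum(bx**2 * w, axis=-1, keepdims=True)
    return (sxy - bx * by * w) / (sxx - bx**2 * w)


def _presso_statistics(instruments: pd.DataFrame, n_sim: int, seed: int):
    """Observed and simulated weighted squared residuals for MR-PRESSO."""
    bx, sx, by, sy, rsids = extract_arrays(instruments)
    j = len(bx)
    if j < 4:
        raise MREstimateError("MR-PRESSO requires at least 4 variants (leave-one-out)")
    if n_sim < 100:
        raise MREstimateError("n_sim must be at least 100")
    w = sy**-2.0

    slopes = _loo_slopes(bx, by, w)
    resid_obs = (by - slopes * bx) ** 2 * w
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(slopes * bx, sy, size=(n_sim, j))
    slopes_star = _loo_slopes(bx_star, by_star, w)
    resid_star = (by_star - slopes_star * bx_star) ** 2 * w
    rss_star = np.sum(resid_star, axis=1)
    return rsids, resid_obs, rss_obs, resid_star, rss_star


def presso_global(
    instruments: pd.DataFrame, n_sim: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """MR-PRESSO global heterogeneity test.

    The observed statistic is the residual sum of squares of each variant
    around the leave-one-out IVW fit, weighted by 1/se_Y².  ``n_sim``
    parametric replicates redraw beta_X*[j] ~ N(beta_X[j], se_X[j]²) and
    beta_Y*[j] ~ N(slope_(-j)*beta_X[j], se_Y[j]²) and recompute the
    statistic; the empirical p-value is (1 + #{sim >= observed})/(n_sim+1).

    Returns ``(rss_observed, global_p)``.
    """
    if seed is None:
        raise MREstimateError("presso_global requires an explicit seed")
    _, _, rss_obs, _, rss_star = _presso_statistics(instruments, n_sim, seed)
    global_p = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)
    return rss_obs, global_p


def presso_outliers(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
    bonferroni: bool = False,
) -> tuple[list, dict]:
    """Per-variant MR-PRESSO outlier test.

    Each variant's observed weighted squared residual is compared against
    its own simulated distribution; variants with empirical p below
    ``alpha_outlier`` are flagged.  No multiplicity correction is applied
    by default; ``bonferroni=True`` divides the threshold by J.

    Returns ``(outlier_rsids, {rsid: p})``.
    """
    if seed is None:
        raise MREstimateError("presso_outliers requires an explicit seed")
    rsids, resid_obs, _, resid_star, _ = _presso_statistics(instruments, n_sim, seed)
    j = len(rsids)
    pvals = (1.0 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1.0)
    threshold = alpha_outlier / j if bonferroni else alpha_outlier
    outliers = [r for r, p in zip(rsids, pvals) if p < threshold]
    if len(outliers) == j:
        raise MREstimateError("every instrument flagged as outlier: no stable regression remains")
    return outliers, {r: float(p) for r, p in zip(rsids, pvals)}


def presso_workflow(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
    alpha_global: float = 0.05,
    effects_model: str = "multiplicative_random",
    bonferroni: bool = False,
) -> PressoReport:
    """Global test, conditional outlier removal, and retest.

    (i) run the global heterogeneity test; (ii) if significant at
    ``alpha_global``, flag and remove outliers; (iii) re-estimate IVW on
    the surviving variants and retest heterogeneity with Q'.  When the
    global test is not significant, the outlier set is empty and the
    adjusted estimate equals the unadjusted IVW.
    """
    if seed is None:
        raise MREstimateError("presso_workflow requires an explicit seed")
    rss_obs, global_p = presso_global(instruments, n_sim, seed)
    report = PressoReport(
        rss_observed=rss_obs, global_p=global_p, n_sim=n_sim, seed=seed
    )
    retained = instruments
    if "exclusion_flag" in retained.columns:
        retained = retained[retained["exclusion_flag"] == "none"]
    if global_p < alpha_global:
        outliers, pvals = presso_outliers(
            instruments, n_sim, seed, alpha_outlier, bonferroni
        )
        report.outliers = outliers
        report.outlier_pvalues = pvals
        retained = retained[~retained["rsid"].astype(str).isin(outliers)]
    report.adjusted = ivw(retained, effects_model=effects_model)
    if len(retained) >= 2:
        report.post_removal = q_prime(retained)
    return report
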