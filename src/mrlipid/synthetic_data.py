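"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of the real inputs — a lipid exposure
GWAS of ~190k individuals and a breast-cancer case-control outcome GWAS of
~229k women — so every pipeline stage can be exercised and its recovery of
the planted truth measured:

* per-variant exposure effects gamma_j (per SD) with GWAS-realistic standard
  errors derived from allele frequency and sample size,
  se_X = 1/sqrt(2*p*(1-p)*n_exposure);
* outcome effects obeying the instrumental-variable identity
  Gamma_j = theta*gamma_j + alpha_j, with case-control standard errors
  se_Y = 1/sqrt(2*p*(1-p)*n_eff), n_eff = n_cases*n_controls/(n_cases+n_controls);
* pleiotropy alpha_j: none, balanced (zero-mean), directional (shifted
  mean) or a few large spiked outliers;
* cross-correlated effects on three lipids through a 3x3 loading matrix,
  to exercise the pleiotropy-filtered (restrictive) instrument selection;
* LD-correlated cis variants with an exponential-decay correlation
  structure, to exercise the correlated-instrument estimators.

One integer seed governs everything through named substreams (Philox keyed
by (seed, stream)), each consuming a fixed number of draws per variant in
variant order, so enlarging J extends the tail of each stream without
perturbing earlier draws.  Identical config + seed gives byte-identical
output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import LDMatrix, LIPIDS
from .sumstats_io import ASSOCIATION_COLUMNS

__all__ = [
    "GLGC_N",
    "BCAC_CASES",
    "BCAC_CONTROLS",
    "SyntheticTruth",
    "simulate_instruments",
    "simulate_harmonized",
    "simulate_multilipid",
    "simulate_ld_block",
    "true_panel_effects",
    "write_summary_stats",
]

# default sample sizes mimic the real consortium scale
GLGC_N = 188_577
BCAC_CASES = 122_977
BCAC_CONTROLS = 105_974

PLEIOTROPY_MODES = ("none", "balanced", "directional", "outlier")

# non-palindromic allele pairs cycled across variants
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))

_STREAMS = {"eaf": 0, "gamma": 1, "alpha": 2, "noise_x": 3, "noise_y": 4, "multilipid": 5, "ld": 6}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible substream of the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.Generator(np.random.Philox(ss))


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset.

    The outcome truth always satisfies Gamma_j = theta*gamma_j + alpha_j.
    """

    theta: float
    gamma: list
    alpha: list
    pleiotropy_mode: str
    outlier_indices: list = field(default_factory=list)
    loading_matrix: list | None = None
    assignments: list | None = None
    n_exposure: int = GLGC_N
    n_cases: int = BCAC_CASES
    n_controls: int = BCAC_CONTROLS
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _alleles(j: int) -> tuple[list, list]:
    ea = [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)][0] for i in range(j)]
    oa = [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)][1] for i in range(j)]
    return ea, oa


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)


def _assoc_frame(rsids, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _two_sided_p(np.asarray(beta), np.asarray(se)),
            "n": n,
        }
    )
    return df[list(ASSOCIATION_COLUMNS) + ["n"]]


def simulate_instruments(
    J: int,
    theta: float,
    pleiotropy_mode: str = "none",
    pleiotropy_scale: float = 0.02,
    n_exposure: int = GLGC_N,
    n_cases: int = BCAC_CASES,
    n_controls: int = BCAC_CONTROLS,
    seed: int = 0,
    pleiotropy_mean: float = 0.05,
    n_outliers: int = 1,
    outlier_sigma: float = 10.0,
    rsid_prefix: str = "rs",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate exposure and outcome summary-statistic tables for J variants.

    Effect-allele frequencies are uniform(0.05, 0.95); true exposure effects
    gamma_j ~ N(0.08, 0.03²) clipped positive (per-SD scale); observed betas
    are drawn around the truth with the GWAS standard errors above.
    Pleiotropy alpha_j by mode:

    * ``none``        — all zero;
    * ``balanced``    — N(0, pleiotropy_scale²);
    * ``directional`` — N(pleiotropy_mean, pleiotropy_scale²);
    * ``outlier``     — zero except ``n_outliers`` variants (the last ones)
      spiked at ``outlier_sigma`` outcome standard errors.

    Alleles are emitted from a non-palindromic cycle so harmonization
    retains every variant.
    """
    if J < 2:
        raise ValueError("J must be at least 2")
    if min(n_exposure, n_cases, n_controls) <= 0:
        raise ValueError("sample sizes must be positive")
    if pleiotropy_mode not in PLEIOTROPY_MODES:
        raise ValueError(f"unknown pleiotropy mode {pleiotropy_mode!r}; expected {PLEIOTROPY_MODES}")

    eaf = _stream(seed, "eaf").uniform(0.05, 0.95, size=J)
    gamma = np.abs(_stream(seed, "gamma").normal(0.08, 0.03, size=J))
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_eff)

    rng_a = _stream(seed, "alpha")
    outlier_idx: list[int] = []
    if pleiotropy_mode == "none":
        alpha = np.zeros(J)
    elif pleiotropy_mode == "balanced":
        alpha = rng_a.normal(0.0, pleiotropy_scale, size=J)
    elif pleiotropy_mode == "directional":
        alpha = rng_a.normal(pleiotropy_mean, pleiotropy_scale, size=J)
    else:
        if not (0 < n_outliers < J):
            raise ValueError("n_outliers must lie in (0, J)")
        alpha = np.zeros(J)
        outlier_idx = list(range(J - n_outliers, J))
        alpha[outlier_idx] = outlier_sigma * se_y[outlier_idx]

    beta_x = _stream(seed, "noise_x").normal(gamma, se_x)
    beta_y = _stream(seed, "noise_y").normal(theta * gamma + alpha, se_y)

    rsids = [f"{rsid_prefix}{i + 1}" for i in range(J)]
    ea, oa = _alleles(J)
    exposure = _assoc_frame(rsids, ea, oa, eaf, beta_x, se_x, n_exposure)
    outcome = _assoc_frame(rsids, ea, oa, eaf, beta_y, se_y, n_cases + n_controls)
    truth = SyntheticTruth(
        theta=float(theta),
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        pleiotropy_mode=pleiotropy_mode,
        outlier_indices=outlier_idx,
        n_exposure=n_exposure,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=int(seed),
    )
    return exposure, outcome, truth


def simulate_harmonized(*args, **kwargs) -> tuple[pd.DataFrame, SyntheticTruth]:
    """``simulate_instruments`` followed by direct pairing into a harmonized table.

    The generator emits consistent alleles and no palindromes, so pairing
    column-for-column is exactly what :func:`mrlipid.sumstats_io.harmonize`
    produces (a test asserts this equivalence); this fast path avoids the
    per-row harmonization loop inside Monte-Carlo calibration studies.
    """
    exposure, outcome, truth = simulate_instruments(*args, **kwargs)
    harmonized = pd.DataFrame(
        {
            "rsid": exposure["rsid"],
            "effect_allele": exposure["effect_allele"],
            "beta_exposure": exposure["beta"],
            "se_exposure": exposure["se"],
            "beta_outcome": outcome["beta"],
            "se_outcome": outcome["se"],
            "eaf_exposure": exposure["eaf"],
            "eaf_outcome": outcome["eaf"],
            "exclusion_flag": "none",
        }
    )
    # exposure orientation: flip the (rare) negative observed exposure betas
    flip = harmonized["beta_exposure"] < 0
    harmonized.loc[flip, "effect_allele"] = exposure.loc[flip, "other_allele"]
    harmonized.loc[flip, "beta_exposure"] *= -1
    harmonized.loc[flip, "beta_outcome"] *= -1
    harmonized.loc[flip, "eaf_exposure"] = 1 - harmonized.loc[flip, "eaf_exposure"]
    harmonized.loc[flip, "eaf_outcome"] = 1 - harmonized.loc[flip, "eaf_outcome"]
    return harmonized, truth


def simulate_multilipid(
    J_total: int,
    loading_matrix: np.ndarray | None = None,
    thresholds: tuple[float, float] = (5e-8, 1e-3),
    seed: int = 0,
    assignments: list | None = None,
    effect_mean: float = 0.10,
    n_exposure: int = GLGC_N,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a three-lipid association panel with planted structure.

    Each variant is assigned one or more lipids (default: round-robin
    single-lipid assignment); its latent effect e_j ~ N(effect_mean,
    (effect_mean/5)²) clipped positive enters the assigned components of a
    raw effect vector, which the 3x3 ``loading_matrix`` mixes across lipids
    (identity = no cross-lipid association).  Observed panel betas add
    frequency-derived GWAS noise; p-values follow.  The truth records the
    assignments so recovery of the comprehensive/restrictive selections is
    checkable against the planted membership.
    """
    L = np.eye(3) if loading_matrix is None else np.asarray(loading_matrix, dtype=float)
    if L.shape != (3, 3):
        raise ValueError("loading matrix must be 3x3")
    if assignments is None:
        assignments = [(i % 3,) for i in range(J_total)]
    if len(assignments) != J_total:
        raise ValueError("assignments length must equal J_total")

    rng = _stream(seed, "multilipid")
    eaf = rng.uniform(0.05, 0.95, size=J_total)
    latent = np.abs(rng.normal(effect_mean, effect_mean / 5.0, size=J_total))
    se = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_exposure)

    raw = np.zeros((J_total, 3))
    for j, lips in enumerate(assignments):
        for k in lips:
            raw[j, int(k)] = latent[j]
    true_beta = raw @ L.T
    noise = rng.normal(0.0, 1.0, size=(J_total, 3)) * se[:, None]
    beta = true_beta + noise

    panel = pd.DataFrame({"rsid": [f"rs{i + 1}" for i in range(J_total)], "eaf": eaf})
    for k, lip in enumerate(LIPIDS):
        panel[f"beta_{lip}"] = beta[:, k]
        panel[f"se_{lip}"] = se
        panel[f"p_{lip}"] = _two_sided_p(beta[:, k], se)
    truth = SyntheticTruth(
        theta=float("nan"),
        gamma=latent.tolist(),
        alpha=[0.0] * J_total,
        pleiotropy_mode="none",
        loading_matrix=L.tolist(),
        assignments=[list(a) for a in assignments],
        n_exposure=n_exposure,
        seed=int(seed),
    )
    return panel, truth


def simulate_ld_block(
    J: int,
    decay_rho: float,
    seed: int = 0,
    theta: float = 0.1,
    n_exposure: int = GLGC_N,
    n_cases: int = BCAC_CASES,
    n_controls: int = BCAC_CONTROLS,
    rsid_prefix: str = "rs",
) -> tuple[LDMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate LD-correlated cis instruments for one gene region.

    Pairwise correlations follow rho_jk = decay_rho^|j-k| (an AR(1)
    structure, positive-definite by construction).  Observed exposure and
    outcome betas are drawn jointly with covariance D * rho * D where D
    holds the per-variant standard errors, so the correlated-instrument
    estimators see exactly the dependence the LD matrix declares.
    """
    if not (0 <= decay_rho < 1):
        raise ValueError("decay_rho must lie in [0, 1)")
    if J < 2:
        raise ValueError("J must be at least 2")
    rng = _stream(seed, "ld")
    idx = np.arange(J)
    rho = decay_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(rho)

    eaf = rng.uniform(0.05, 0.95, size=J)
    gamma = np.abs(rng.normal(0.08, 0.03, size=J))
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_eff)

    beta_x = gamma + se_x * (chol @ rng.standard_normal(J))
    beta_y = theta * gamma + se_y * (chol @ rng.standard_normal(J))

    rsids = [f"{rsid_prefix}{i + 1}" for i in range(J)]
    ea, oa = _alleles(J)
    exposure = _assoc_frame(rsids, ea, oa, eaf, beta_x, se_x, n_exposure)
    outcome = _assoc_frame(rsids, ea, oa, eaf, beta_y, se_y, n_cases + n_controls)
    truth = SyntheticTruth(
        theta=float(theta),
        gamma=gamma.tolist(),
        alpha=[0.0] * J,
        pleiotropy_mode="none",
        n_exposure=n_exposure,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=int(seed),
    )
    return LDMatrix(rsids, rho), exposure, outcome, truth


def true_panel_effects(truth: SyntheticTruth) -> np.ndarray:
    """Reconstruct the noise-free (J, 3) lipid effect matrix of a panel truth."""
    if truth.assignments is None or truth.loading_matrix is None:
        raise ValueError("truth does not describe a multi-lipid panel")
    J = len(truth.assignments)
    raw = np.zeros((J, 3))
    for j, lips in enumerate(truth.assignments):
        for k in lips:
            raw[j, int(k)] = truth.gamma[j]
    return raw @ np.asarray(truth.loading_matrix).T


def write_summary_stats(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write an association table in the dialect ``read_summary_stats`` reads.

    Floats use repr-round-trip precision so write-then-read is lossless.
    """
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
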