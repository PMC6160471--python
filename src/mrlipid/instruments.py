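"""Instrument selection: lipid panels and cis gene-region drug-target sets.

Three instrument sets drive the analysis:

* **comprehensive** — all panel variants genome-wide significantly associated
  (P < 5e-8 by default) with the target lipid;
* **restrictive** — the comprehensive set minus variants associated at
  P < 1e-3 with either of the other two lipids (a pleiotropy filter);
* **gene region** — candidate variants inside a drug-target gene window,
  greedily accepted in order of increasing target-lipid p-value subject to
  pairwise r² < 0.4 against everything already accepted (cis instruments in
  moderate linkage disequilibrium, analysed later with LD-aware estimators).

A lipid panel is a DataFrame with one row per variant and lipid-suffixed
statistic columns (``beta_ldl, se_ldl, p_ldl, beta_hdl, ...``).  LD is a
signed correlation matrix; r² is its elementwise square, and the signed
matrix is retained for correlated-instrument estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LIPIDS",
    "InstrumentError",
    "LDMatrix",
    "GeneRegionSpec",
    "read_lipid_panel",
    "select_comprehensive",
    "select_restrictive",
    "select_gene_region",
    "load_ld_matrix",
    "write_ld_matrix",
]

#: trait keys used as column suffixes in a lipid panel
LIPIDS = ("ldl", "hdl", "tg")

P_GWS_DEFAULT = 5e-8
P_SECONDARY_DEFAULT = 1e-3
R2_MAX_DEFAULT = 0.4


class InstrumentError(ValueError):
    """Raised when an instrument set cannot be constructed."""


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix over a list of variants.

    ``values[j, k]`` is the correlation rho between variants ``rsids[j]``
    and ``rsids[k]``; r² used for pruning is ``rho**2``.  Symmetric with
    unit diagonal.
    """

    rsids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.rsids = [str(r) for r in self.rsids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InstrumentError("LD matrix must be square")
        if v.shape[0] != len(self.rsids):
            raise InstrumentError("LD matrix dimension does not match rsid list")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-6:
            raise InstrumentError(f"LD matrix asymmetric beyond tolerance ({asym:.2e})")
        v = (v + v.T) / 2.0
        if v.size and np.max(np.abs(np.diag(v) - 1.0)) > 1e-6:
            raise InstrumentError("LD matrix diagonal must be 1")
        if v.size and np.max(np.abs(v)) > 1.0 + 1e-6:
            raise InstrumentError("LD correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = v

    def subset(self, rsids: list) -> "LDMatrix":
        """Submatrix over ``rsids``, preserving their order."""
        pos = {r: i for i, r in enumerate(self.rsids)}
        missing = [r for r in rsids if r not in pos]
        if missing:
            raise InstrumentError(f"variant(s) missing from LD matrix: {', '.join(missing)}")
        idx = [pos[r] for r in rsids]
        return LDMatrix(list(rsids), self.values[np.ix_(idx, idx)])

    def rho(self, a: str, b: str) -> float:
        pos = {r: i for i, r in enumerate(self.rsids)}
        return float(self.values[pos[a], pos[b]])


@dataclass
class GeneRegionSpec:
    """Candidate cis variants for one drug-target gene.

    ``candidates`` is a DataFrame with columns ``rsid`` and ``pvalue``
    (target-lipid association p); ``window`` is descriptive metadata for the
    gene window the candidates were drawn from and is never recomputed.
    """

    gene: str
    target_lipid: str
    candidates: pd.DataFrame
    window: str = "gene +/- 100 kb"
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneRegionSpec":
        cand = pd.DataFrame(d["candidates"])
        return cls(
            gene=d["gene"],
            target_lipid=d["target_lipid"],
            candidates=cand[["rsid", "pvalue"]],
            window=d.get("window", "gene +/- 100 kb"),
            metadata=d.get("metadata", {}),
        )


def read_lipid_panel(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a lipid panel TSV (rsid + beta/se/p columns per lipid)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"rsid": str}, float_precision="round_trip")
    required = ["rsid"] + [f"{s}_{lip}" for lip in LIPIDS for s in ("beta", "se", "p")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InstrumentError(f"lipid panel missing column(s): {', '.join(missing)}")
    return df


def select_comprehensive(
    panel: pd.DataFrame, lipid: str, p_gws: float = P_GWS_DEFAULT
) -> list[str]:
    """All panel variants with target-lipid p below genome-wide significance.

    Order-stable by panel row order.  Empty selection is a hard error (no
    instrument exists for this lipid at the chosen threshold).
    """
    if lipid not in LIPIDS:
        raise InstrumentError(f"unknown lipid {lipid!r}; expected one of {LIPIDS}")
    if not (0 < p_gws < 1):
        raise InstrumentError("p_gws must lie in (0, 1)")
    sel = panel.loc[panel[f"p_{lipid}"] < p_gws, "rsid"].tolist()
    if not sel:
        raise InstrumentError(f"no variant reaches p < {p_gws:g} for {lipid}")
    return sel


def select_restrictive(
    panel: pd.DataFrame,
    lipid: str,
    p_gws: float = P_GWS_DEFAULT,
    p_secondary: float = P_SECONDARY_DEFAULT,
) -> list[str]:
    """Comprehensive set minus variants associated with either other lipid.

    A variant is excluded when its p-value for any of the two non-target
    lipids falls below ``p_secondary``; this strips likely-pleiotropic
    instruments at the cost of instrument strength.
    """
    if not (0 < p_secondary <= 1):
        raise InstrumentError("p_secondary must lie in (0, 1]")
    comp = select_comprehensive(panel, lipid, p_gws)
    others = [l for l in LIPIDS if l != lipid]
    ix = panel.set_index("rsid")
    sel = [
        r for r in comp
        if not any(ix.loc[r, f"p_{o}"] < p_secondary for o in others)
    ]
    if not sel:
        raise InstrumentError(
            f"restrictive selection for {lipid} is empty at p_secondary {p_secondary:g}"
        )
    return sel


def select_gene_region(
    region: GeneRegionSpec,
    ld: LDMatrix,
    p_gws: float = P_GWS_DEFAULT,
    r2_max: float = R2_MAX_DEFAULT,
) -> list[str]:
    """Greedy LD-pruned selection of cis instruments for one gene.

    Candidates with target-lipid p < ``p_gws`` are ranked by ascending
    p-value (ties broken by rsid lexicographic order so the result is
    deterministic) and accepted iff their squared correlation with every
    previously accepted variant stays below ``r2_max``.
    """
    if not (0 < r2_max <= 1):
        raise InstrumentError("r2_max must lie in (0, 1]")
    cand = region.candidates
    sig = cand[cand["pvalue"] < p_gws]
    if sig.empty:
        raise InstrumentError(f"no genome-wide-significant candidate in {region.gene}")
    missing = [r for r in sig["rsid"] if r not in ld.rsids]
    if missing:
        raise InstrumentError(
            f"candidate(s) missing from LD matrix for {region.gene}: {', '.join(missing)}"
        )
    ranked = sig.sort_values(["pvalue", "rsid"], kind="mergesort")
    selected: list[str] = []
    for r in ranked["rsid"]:
        if all(ld.rho(r, s) ** 2 < r2_max for s in selected):
            selected.append(r)
    return selected


def load_ld_matrix(path: str | Path, delimiter: str = "\t") -> LDMatrix:
    """Read a square LD correlation matrix keyed by rsid.

    Expects the first row and first column to carry rsids.  Mild asymmetry
    (< 1e-6, e.g. from decimal truncation) is symmetrized by averaging;
    anything larger, a non-unit diagonal or out-of-range entries are hard
    errors.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    rsids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != rsids:
        raise InstrumentError("LD matrix row and column rsids differ")
    return LDMatrix(rsids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write an LD matrix in the dialect ``load_ld_matrix`` reads, full precision."""
    pd.DataFrame(ld.values, index=ld.rsids, columns=ld.rsids).to_csv(
        path, sep=delimiter, float_format="%.17g"
    )
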