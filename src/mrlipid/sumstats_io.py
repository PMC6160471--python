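"""Reading, validation, orientation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant associations from an
exposure GWAS (here blood lipids, effects per standard deviation) with those
from an outcome GWAS (breast cancer case-control, effects on the log-odds
scale).  Before any estimation the two tables must be placed on a common
effect allele: exposure effects are oriented to the lipid-increasing allele,
outcome rows are matched to the exposure alleles directly or by swapping
(negating the log-odds and complementing the frequency), palindromic variants
whose strand cannot be resolved from allele frequencies are dropped, and
cross-study allele-frequency consistency is checked.

The canonical in-memory containers are pandas DataFrames:

* association table — columns ``rsid, effect_allele, other_allele, eaf, beta,
  se, pvalue`` (optional ``n``), one row per variant;
* harmonized table — columns ``rsid, effect_allele, beta_exposure,
  se_exposure, beta_outcome, se_outcome, eaf_exposure, eaf_outcome,
  exclusion_flag``.

``exclusion_flag`` is ``none`` for rows that enter estimation and otherwise
records why a variant was removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ASSOCIATION_COLUMNS",
    "HARMONIZED_COLUMNS",
    "EXCLUSION_FLAGS",
    "SumstatsError",
    "HarmonizationLog",
    "read_summary_stats",
    "validate_associations",
    "is_palindromic",
    "orient_to_increasing_allele",
    "harmonize",
    "write_harmonized",
]

#: canonical column order of a validated association table
ASSOCIATION_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")

#: fixed column order of the harmonized output table
HARMONIZED_COLUMNS = (
    "rsid",
    "effect_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "exclusion_flag",
)

EXCLUSION_FLAGS = (
    "none",
    "palindromic_ambiguous",
    "allele_mismatch",
    "missing_in_outcome",
    "multiallelic_conflict",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised for unrecoverable problems in summary-statistic inputs."""


@dataclass
class HarmonizationLog:
    """Per-variant audit trail of the harmonization step.

    ``records`` holds one dict per input exposure variant with the action
    taken (kept / flipped outcome alleles) and the exclusion reason if any;
    ``counts`` aggregates exclusion reasons.  The conservation invariant
    ``n_input == n_retained + n_excluded`` always holds.
    """

    n_input: int = 0
    n_retained: int = 0
    n_excluded: int = 0
    counts: dict = field(default_factory=dict)
    records: list = field(default_factory=list)

    def add(self, rsid: str, flag: str, flipped: bool = False, note: str = "") -> None:
        rec = {"rsid": rsid, "exclusion_flag": flag, "outcome_alleles_swapped": flipped}
        if note:
            rec["note"] = note
        self.records.append(rec)
        self.n_input += 1
        if flag == "none":
            self.n_retained += 1
        else:
            self.n_excluded += 1
            self.counts[flag] = self.counts.get(flag, 0) + 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_summary_stats(
    path: str | Path,
    column_map: dict | None = None,
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistics table into a validated frame.

    Parameters
    ----------
    path
        Delimited text file with one header row; gzip-compressed input is
        accepted (inferred from the ``.gz`` suffix by pandas).
    column_map
        Mapping from canonical names (``rsid``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, optionally
        ``n``) to the column names used in the file.  Canonical names absent
        from the map are looked up verbatim.
    delimiter
        Field separator, tab by default.

    Returns
    -------
    DataFrame with the canonical columns, alleles upper-cased, rows failing
    the per-row invariants dropped and reported in ``df.attrs['rejected']``.

    Raises
    ------
    SumstatsError
        If a mandatory column is missing or rsids are duplicated.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"summary-statistics file not found: {path}")
    raw = pd.read_csv(path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    column_map = dict(column_map or {})
    rename = {}
    missing = []
    mandatory = list(ASSOCIATION_COLUMNS)
    for canon in mandatory + ["n"]:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in mandatory and canon != "eaf":
            missing.append(canon)
    if missing:
        raise SumstatsError(f"missing mandatory column(s): {', '.join(missing)}")
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    keep = [c for c in list(ASSOCIATION_COLUMNS) + ["n"] if c in df.columns]
    df = df[keep].copy()
    return validate_associations(df)


def validate_associations(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the association-table invariants on a frame.

    Row-level violations (non-positive se, out-of-range eaf or p-value,
    identical alleles) drop the row and record it; duplicated rsids are a
    table-level hard error.
    """
    df = df.copy()
    df["rsid"] = df["rsid"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    dup = df["rsid"][df["rsid"].duplicated()].unique()
    if len(dup):
        raise SumstatsError(f"duplicate rsid(s): {', '.join(sorted(dup))}")

    rejected = []
    ok = pd.Series(True, index=df.index)
    checks = [
        (~df["se"].gt(0), "se not > 0"),
        (df["beta"].isna(), "missing beta"),
        (~(df["pvalue"].gt(0) & df["pvalue"].le(1)), "pvalue outside (0, 1]"),
        (df["eaf"].notna() & ~(df["eaf"].ge(0) & df["eaf"].le(1)), "eaf outside [0, 1]"),
        (df["effect_allele"] == df["other_allele"], "effect allele equals other allele"),
    ]
    for bad, reason in checks:
        newly = bad & ok
        for rsid in df.loc[newly, "rsid"]:
            rejected.append({"rsid": rsid, "reason": reason})
        ok &= ~bad
    out = df[ok].reset_index(drop=True)
    out.attrs["rejected"] = rejected
    return out


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous).

    Multi-base alleles (indels) cannot be palindromic in this sense and
    return False with a warning.
    """
    a, b = str(effect_allele).upper(), str(other_allele).upper()
    if len(a) != 1 or len(b) != 1 or a not in _COMPLEMENT or b not in _COMPLEMENT:
        warnings.warn(
            f"non-single-base alleles ({a}/{b}) treated as non-palindromic",
            stacklevel=2,
        )
        return False
    return _COMPLEMENT[a] == b


def orient_to_increasing_allele(assoc: pd.DataFrame) -> pd.DataFrame:
    """Align every row to the trait-increasing allele.

    Rows with negative beta have their alleles swapped, beta negated and eaf
    complemented; se and p-value are untouched.  Idempotent: applying twice
    equals applying once.
    """
    df = assoc.copy()
    flip = df["beta"] < 0
    ea = df.loc[flip, "effect_allele"].copy()
    df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
    df.loc[flip, "other_allele"] = ea
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    return df


def _match_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """Classify outcome alleles against exposure alleles.

    Returns ``'direct'``, ``'swap'`` or None (no match either way).
    """
    if ea_y == ea_x and oa_y == oa_x:
        return "direct"
    if ea_y == oa_x and oa_y == ea_x:
        return "swap"
    return None


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_ambiguity_limit: float = 0.42,
    freq_tolerance: float = 0.20,
) -> tuple[pd.DataFrame, HarmonizationLog]:
    """Pair exposure and outcome associations on a common effect allele.

    The exposure table must already be oriented to the increasing allele
    (this function orients it defensively).  For each exposure variant:

    * absent from the outcome table -> ``missing_in_outcome`` (the study's
      handling of unavailable variants; no proxy search is attempted);
    * outcome alleles matching by swap -> beta_outcome negated and
      eaf_outcome complemented;
    * alleles matching neither directly nor by swap ->
      ``multiallelic_conflict``;
    * palindromic pairs (A/T, C/G) are kept only when both allele
      frequencies sit on the same side of 0.5 and each is at least
      ``0.5 - maf_ambiguity_limit`` away from 0.5 — i.e. a minor-allele
      frequency above ``maf_ambiguity_limit`` in either study makes the
      strand unresolvable (``palindromic_ambiguous``);
    * surviving rows with ``|eaf_exposure - eaf_outcome| > freq_tolerance``
      are flagged ``allele_mismatch`` (cross-study frequency check).

    Returns the harmonized table (every input exposure variant appears
    exactly once, retained or excluded) and a :class:`HarmonizationLog`.
    """
    if not (0 <= maf_ambiguity_limit <= 0.5):
        raise ValueError("maf_ambiguity_limit must lie in [0, 0.5]")
    exposure = orient_to_increasing_allele(exposure)
    out_ix = outcome.set_index("rsid")
    if not exposure["rsid"].isin(out_ix.index).any():
        raise SumstatsError("no overlapping variants between exposure and outcome")

    log = HarmonizationLog()
    rows = []
    min_dist = 0.5 - maf_ambiguity_limit

    for row in exposure.itertuples(index=False):
        rsid = row.rsid
        rec = {
            "rsid": rsid,
            "effect_allele": row.effect_allele,
            "beta_exposure": row.beta,
            "se_exposure": row.se,
            "beta_outcome": np.nan,
            "se_outcome": np.nan,
            "eaf_exposure": row.eaf,
            "eaf_outcome": np.nan,
            "exclusion_flag": "none",
        }
        if rsid not in out_ix.index:
            rec["exclusion_flag"] = "missing_in_outcome"
            rows.append(rec)
            log.add(rsid, "missing_in_outcome")
            continue
        orow = out_ix.loc[rsid]
        match = _match_alleles(
            row.effect_allele, row.other_allele,
            str(orow["effect_allele"]).upper(), str(orow["other_allele"]).upper(),
        )
        if match is None:
            rec["exclusion_flag"] = "multiallelic_conflict"
            rows.append(rec)
            log.add(rsid, "multiallelic_conflict")
            continue
        flip = match == "swap"
        beta_y = -orow["beta"] if flip else orow["beta"]
        eaf_y = orow["eaf"]
        if flip and pd.notna(eaf_y):
            eaf_y = 1.0 - eaf_y
        rec["beta_outcome"] = beta_y
        rec["se_outcome"] = orow["se"]
        rec["eaf_outcome"] = eaf_y

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            palin = is_palindromic(row.effect_allele, row.other_allele)
        if palin:
            ambiguous = True
            if pd.notna(row.eaf) and pd.notna(eaf_y):
                same_side = (row.eaf - 0.5) * (eaf_y - 0.5) > 0
                far = abs(row.eaf - 0.5) >= min_dist and abs(eaf_y - 0.5) >= min_dist
                ambiguous = not (same_side and far)
            if ambiguous:
                rec["exclusion_flag"] = "palindromic_ambiguous"
                rows.append(rec)
                log.add(rsid, "palindromic_ambiguous", flipped=flip)
                continue
        if (
            pd.notna(row.eaf)
            and pd.notna(eaf_y)
            and abs(row.eaf - eaf_y) > freq_tolerance
        ):
            rec["exclusion_flag"] = "allele_mismatch"
            rows.append(rec)
            log.add(
                rsid, "allele_mismatch", flipped=flip,
                note=f"|eaf_exposure - eaf_outcome| = {abs(row.eaf - eaf_y):.3f}",
            )
            continue
        rows.append(rec)
        log.add(rsid, "none", flipped=flip)

    harmonized = pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))
    assert log.n_input == log.n_retained + log.n_excluded
    return harmonized, log


def write_harmonized(harmonized: pd.DataFrame, path: str | Path) -> None:
    """Write the harmonized table as TSV in the fixed column order."""
    harmonized[list(HARMONIZED_COLUMNS)].to_csv(path, sep="\t", index=False)
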