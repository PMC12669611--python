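"""Reading, validation and harmonization of GWAS summary statistics.

The canonical per-study layout is a delimited text table (TSV by default,
gzip-transparent) with columns

    variant_id  effect_allele  other_allele  eaf  beta  se  p  n

``eaf`` and ``n`` may be missing.  External files with different headers are
mapped onto this layout through a ``column_map`` of logical field ->
column name.  Harmonization aligns an incidence study and a progression
study on a shared effect allele per variant, flipping the progression sign
where the allele pair is swapped and (by default) discarding
strand-ambiguous A/T and C/G variants, for which the two studies' strand
conventions cannot be checked from summary data alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: logical fields every study file must provide
MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "p")
#: optional logical fields
OPTIONAL_FIELDS = ("eaf", "n")
CANONICAL_COLUMNS = MANDATORY_FIELDS[:3] + ("eaf",) + MANDATORY_FIELDS[3:] + ("n",)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Malformed summary-statistics input (missing columns, bad values)."""


@dataclass
class HarmonizeCounts:
    """Bookkeeping from :func:`harmonize`."""

    kept: int = 0
    flipped: int = 0
    dropped_ambiguous: int = 0
    dropped_mismatch: int = 0
    dropped_not_shared: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AnalysisTable:
    """Harmonized incidence + progression estimates, one row per variant.

    ``df`` columns: variant_id, effect_allele, other_allele, eaf,
    beta_inc, se_inc, p_inc, n_inc, beta_prog, se_prog, p_prog, n_prog.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    counts: HarmonizeCounts | None = None

    def __post_init__(self) -> None:
        ids = self.df["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SumstatsError(f"duplicate variant_id in analysis table: {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path, provenance: dict | None = None) -> "AnalysisTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        missing = [c for c in _ANALYSIS_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsError(f"analysis table {path} missing columns: {missing}")
        return cls(df=df, provenance=provenance or {"source": str(path)})


_ANALYSIS_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf",
    "beta_inc", "se_inc", "p_inc", "n_inc",
    "beta_prog", "se_prog", "p_prog", "n_prog",
]


def read_sumstats(
    path,
    column_map: dict | None = None,
    sep: str = "\t",
    validate_p: bool = True,
) -> pd.DataFrame:
    """Read one study's summary statistics into the canonical layout.

    Parameters
    ----------
    path
        Delimited text file with a header row; ``.gz`` handled transparently.
    column_map
        Mapping of logical field name (see :data:`MANDATORY_FIELDS` /
        :data:`OPTIONAL_FIELDS`) to the column name in the file.  Omitted
        logical fields default to their own name.
    sep
        Field delimiter.
    validate_p
        If true, warn when reported p-values are grossly inconsistent with
        the two-sided normal p implied by beta/se (rounding in published
        meta-analyses makes small discrepancies common, so this never
        rejects rows).

    Returns
    -------
    DataFrame with the canonical columns; rows with missing beta or a
    non-positive/missing SE are dropped (count logged).
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])

    out = {}
    missing = []
    for fld in MANDATORY_FIELDS:
        col = column_map.get(fld, fld)
        if col not in raw.columns:
            missing.append(fld)
        else:
            out[fld] = raw[col]
    if missing:
        raise SumstatsError(
            f"{path}: mandatory fields not found: {missing} "
            f"(map them with column_map; available columns: {list(raw.columns)})"
        )
    for fld in OPTIONAL_FIELDS:
        col = column_map.get(fld, fld)
        out[fld] = raw[col] if col in raw.columns else np.nan

    df = pd.DataFrame(out)
    for col in ("beta", "se", "p", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    df["variant_id"] = df["variant_id"].astype(str)

    bad = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("read_sumstats(%s): dropped %d rows with missing beta or SE <= 0", path, n_bad)
    df = df.loc[~bad].reset_index(drop=True)

    if validate_p and len(df):
        with np.errstate(divide="ignore", invalid="ignore"):
            implied = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        ok = np.isfinite(df["p"])
        # order-of-magnitude agreement; published p-values are rounded
        off = ok & (np.abs(np.log10(np.clip(df["p"], 1e-300, 1.0))
                           - np.log10(np.clip(implied, 1e-300, 1.0))) > 1.0)
        if off.any():
            warnings.warn(
                f"{path}: {int(off.sum())} rows have p-values inconsistent with "
                "|beta/se| under a two-sided normal approximation",
                stacklevel=2,
            )
    return df[list(CANONICAL_COLUMNS)]


def write_sumstats(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a canonical per-study table (inverse of :func:`read_sumstats`)."""
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = a1.map(_COMPLEMENT)
    return comp.notna() & (comp == a2)


def harmonize(
    incidence: pd.DataFrame,
    progression: pd.DataFrame,
    keep_ambiguous: bool = False,
    provenance: dict | None = None,
) -> AnalysisTable:
    """Join incidence and progression studies on a common effect allele.

    Variants present in both studies are kept.  Where the progression
    study reports the swapped allele pair, its beta sign is flipped and its
    eaf replaced by ``1 - eaf``.  Strand-ambiguous variants (A/T, C/G) are
    dropped unless ``keep_ambiguous``; allele pairs that neither match nor
    swap are dropped and counted, never fatal.
    """
    counts = HarmonizeCounts()
    inc = incidence.set_index("variant_id", drop=False)
    pro = progression.set_index("variant_id", drop=False)
    if inc.index.duplicated().any() or pro.index.duplicated().any():
        raise SumstatsError("duplicate variant_id within a study")

    shared = inc.index.intersection(pro.index)
    counts.dropped_not_shared = (len(inc) - len(shared)) + (len(pro) - len(shared))
    inc = inc.loc[shared]
    pro = pro.loc[shared]

    if not keep_ambiguous:
        amb = _is_ambiguous(inc["effect_allele"], inc["other_allele"])
        counts.dropped_ambiguous = int(amb.sum())
        inc, pro = inc.loc[~amb], pro.loc[~amb]

    same = (inc["effect_allele"] == pro["effect_allele"]) & (inc["other_allele"] == pro["other_allele"])
    swapped = (inc["effect_allele"] == pro["other_allele"]) & (inc["other_allele"] == pro["effect_allele"])
    mismatch = ~(same | swapped)
    counts.dropped_mismatch = int(mismatch.sum())
    counts.flipped = int(swapped.sum())

    inc, pro = inc.loc[~mismatch], pro.loc[~mismatch]
    swapped = swapped.loc[~mismatch]

    beta_prog = pro["beta"].where(~swapped, -pro["beta"])
    eaf_prog = pro["eaf"].where(~swapped, 1.0 - pro["eaf"])

    df = pd.DataFrame({
        "variant_id": inc["variant_id"],
        "effect_allele": inc["effect_allele"],
        "other_allele": inc["other_allele"],
        "eaf": inc["eaf"].fillna(eaf_prog),
        "beta_inc": inc["beta"],
        "se_inc": inc["se"],
        "p_inc": inc["p"],
        "n_inc": inc["n"],
        "beta_prog": beta_prog,
        "se_prog": pro["se"],
        "p_prog": pro["p"],
        "n_prog": pro["n"],
    }).reset_index(drop=True)
    counts.kept = len(df)
    logger.info("harmonize: kept=%d flipped=%d dropped_ambiguous=%d dropped_mismatch=%d",
                counts.kept, counts.flipped, counts.dropped_ambiguous, counts.dropped_mismatch)
    return AnalysisTable(df=df, provenance=provenance or {}, counts=counts)


def add_lead_variants(table: AnalysisTable, extra: pd.DataFrame) -> AnalysisTable:
    """Union a harmonized table with extra (already harmonized) records.

    Used to re-add progression lead variants removed by LD clumping on the
    incidence p-value.  De-duplicates on variant_id; records already in
    ``table`` win ties.
    """
    if len(extra) == 0:
        return table
    missing = [c for c in _ANALYSIS_COLUMNS if c not in extra.columns]
    if missing:
        raise SumstatsError(f"extra records missing columns: {missing}")
    merged = pd.concat([table.df, extra[_ANALYSIS_COLUMNS]], ignore_index=True)
    merged = merged.drop_duplicates(subset="variant_id", keep="first").reset_index(drop=True)
    return AnalysisTable(df=merged, provenance=table.provenance, counts=table.counts)
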