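"""GWAS summary-statistic tables: reading, validation, and harmonization.

A summary-statistic table holds one association result per variant: the
estimated per-allele effect (phenotype-SD units for quantitative traits,
log-odds for binary traits), its standard error, p-value, imputation info
score, sample size, and optionally the effect-allele frequency and a
genetic-map position in centimorgans.

Harmonization joins an exposure table and an outcome table on shared
variants, re-signs outcome effects onto the exposure's effect allele
(resolving strand flips through reverse complements), and drops variants
that cannot be used: palindromic allele pairs (A/T or C/G, whose strand
is unresolvable from alleles alone), variants with imputation info below
a threshold on either side, and variants whose allele sets are
incompatible.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    EmptyIntersectionError,
    SumstatFormatError,
    SumstatValidationError,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO", "N"]
OPTIONAL_COLUMNS = ["CM", "EAF"]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: relative tolerance when cross-checking the stated p-value against the
#: two-sided normal p implied by |beta/se|
P_CONSISTENCY_RTOL = 0.10


def is_palindromic(a1: str, a2: str) -> bool:
    """True if the allele pair is A/T or C/G (strand-ambiguous)."""
    return frozenset((a1, a2)) in _PALINDROMIC_PAIRS


def reverse_complement(allele: str) -> str:
    return _COMPLEMENT[allele]


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association result for a single trait."""

    variant_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    info: float
    n: int
    pos_cm: Optional[float] = None
    eaf: Optional[float] = None


@dataclass
class SumstatTable:
    """A validated summary-statistic table for one trait.

    ``data`` is a DataFrame with the canonical columns ``SNP CHR BP A1 A2
    BETA SE P INFO N`` plus optional ``CM`` and ``EAF``; variant ids are
    unique. ``prevalence`` is required for binary traits (it drives the
    liability-scale conversion of variance explained); ``case_fraction``
    is the fraction of cases in the GWAS sample and falls back to
    ``prevalence`` when not given.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    data: pd.DataFrame
    prevalence: Optional[float] = None
    case_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )
        if self.trait_type == "binary":
            if self.prevalence is None:
                raise ConfigurationError(
                    f"binary trait {self.trait_name!r} requires a prevalence"
                )
            if not 0.0 < self.prevalence < 1.0:
                raise ConfigurationError("prevalence must lie in (0, 1)")
        dups = self.data["SNP"][self.data["SNP"].duplicated()].unique()
        if len(dups):
            raise SumstatValidationError(
                [(int(i), f"duplicate variant_id {v!r}")
                 for i, v in self.data["SNP"][self.data["SNP"].duplicated(keep=False)].items()]
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> pd.Series:
        return self.data["SNP"]

    def records(self) -> Iterator[SumstatRecord]:
        """Iterate rows as :class:`SumstatRecord` objects."""
        has_cm = "CM" in self.data.columns
        has_eaf = "EAF" in self.data.columns
        for row in self.data.itertuples(index=False):
            yield SumstatRecord(
                variant_id=row.SNP,
                chrom=str(row.CHR),
                pos_bp=int(row.BP),
                effect_allele=row.A1,
                other_allele=row.A2,
                beta=float(row.BETA),
                se=float(row.SE),
                pvalue=float(row.P),
                info=float(row.INFO),
                n=int(row.N),
                pos_cm=float(row.CM) if has_cm and np.isfinite(row.CM) else None,
                eaf=float(row.EAF) if has_eaf and np.isfinite(row.EAF) else None,
            )


def _validate_rows(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Return (row_index, message) for every row violating a field invariant."""
    problems: list[tuple[int, str]] = []

    def flag(mask: pd.Series, message: str) -> None:
        for i in df.index[mask.fillna(True)]:
            problems.append((int(i), message))

    flag(~df["A1"].isin(_BASES), "effect allele not one of A/C/G/T")
    flag(~df["A2"].isin(_BASES), "other allele not one of A/C/G/T")
    flag(df["A1"] == df["A2"], "effect and other allele identical")
    flag(~(df["SE"] > 0), "se must be > 0")
    flag(~((df["P"] > 0) & (df["P"] <= 1)), "pvalue must lie in (0, 1]")
    flag(~((df["INFO"] >= 0) & (df["INFO"] <= 1)), "info must lie in [0, 1]")
    flag(~(df["N"] > 0), "n must be a positive integer")
    flag(~(df["BP"] > 0), "pos_bp must be a positive integer")
    if "EAF" in df.columns:
        bad_eaf = df["EAF"].notna() & ~((df["EAF"] > 0) & (df["EAF"] < 1))
        flag(bad_eaf, "eaf must lie in (0, 1)")

    # p-value vs |beta/se| consistency under a two-sided normal test;
    # checked in log space, which is equivalent to relative tolerance on p
    ok_rows = ~df.index.isin([i for i, _ in problems])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["BETA"] / df["SE"])
        expected = 2.0 * stats.norm.sf(z)
        checkable = ok_rows & (expected > 0) & df["P"].notna() & (df["P"] > 0)
        rel = np.abs(np.log(df["P"].where(checkable, 1.0)) - np.log(np.where(expected > 0, expected, 1.0)))
    inconsistent = checkable & (rel > np.log1p(P_CONSISTENCY_RTOL))
    flag(pd.Series(inconsistent, index=df.index),
         "pvalue inconsistent with two-sided normal test of beta/se")
    problems.sort(key=lambda t: t[0])
    return problems


def read_sumstats(
    path,
    trait_name: str,
    trait_type: str = "quantitative",
    prevalence: Optional[float] = None,
    case_fraction: Optional[float] = None,
) -> SumstatTable:
    """Read a tab-separated summary-statistic file into a validated table.

    The header must name ``SNP CHR BP A1 A2 BETA SE P INFO N``; ``CM`` and
    ``EAF`` are optional. Gzip-compressed files (``.gz``) are accepted.
    Rows violating field invariants abort the read with a row-indexed
    :class:`~mrbattery.errors.SumstatValidationError` (indices are
    0-based data-row positions).
    """
    path = Path(path)
    if not path.exists():
        raise SumstatFormatError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"SNP": str, "CHR": str, "A1": str, "A2": str},
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    keep = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    problems = _validate_rows(df)
    if problems:
        raise SumstatValidationError(problems)
    return SumstatTable(
        trait_name=trait_name,
        trait_type=trait_type,
        data=df.reset_index(drop=True),
        prevalence=prevalence,
        case_fraction=case_fraction,
    )


def write_sumstats(table: SumstatTable, path) -> None:
    """Write a table in the canonical tab-separated dialect (gzip if ``.gz``)."""
    path = Path(path)
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.data.columns]
    text = table.data[cols].to_csv(sep="\t", index=False)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


# ---------------------------------------------------------------------------
# allele alignment


@dataclass(frozen=True)
class AlignResult:
    """Outcome of aligning one outcome record onto an exposure record.

    ``verdict`` is one of ``kept``, ``palindromic``, ``low_info``,
    ``allele_mismatch``. For ``kept``, ``beta_out`` (and ``eaf_out`` when
    present) are expressed on the exposure's effect allele.
    """

    verdict: str
    beta_out: Optional[float] = None
    eaf_out: Optional[float] = None


def align_alleles(exp: SumstatRecord, out: SumstatRecord, min_info: float = 0.9) -> AlignResult:
    """Align an outcome record's effect onto the exposure's effect allele.

    Palindromic allele pairs (either side) are excluded outright; then
    variants where either side's info score falls below ``min_info``;
    then allele sets that match neither directly nor as reverse
    complements. When the outcome's effect allele equals the exposure's
    *other* allele (directly or on the opposite strand), the outcome beta
    is negated and its allele frequency replaced by its complement.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError("records must share a variant_id")
    if is_palindromic(exp.effect_allele, exp.other_allele) or is_palindromic(
        out.effect_allele, out.other_allele
    ):
        return AlignResult("palindromic")
    if exp.info < min_info or out.info < min_info:
        return AlignResult("low_info")

    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    rc1, rc2 = reverse_complement(o1), reverse_complement(o2)
    if (o1, o2) == (e1, e2) or (rc1, rc2) == (e1, e2):
        return AlignResult("kept", beta_out=out.beta, eaf_out=out.eaf)
    if (o1, o2) == (e2, e1) or (rc1, rc2) == (e2, e1):
        eaf = None if out.eaf is None else 1.0 - out.eaf
        return AlignResult("kept", beta_out=-out.beta, eaf_out=eaf)
    return AlignResult("allele_mismatch")


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizedPair:
    """Exposure/outcome records joined on shared variants, alleles aligned.

    ``rows`` carries one record per usable shared variant with columns
    ``SNP CHR BP CM beta_exp se_exp p_exp eaf_exp beta_out se_out p_out``,
    outcome effects re-signed onto the exposure's effect allele, sorted by
    ascending (chromosome, base-pair position). Drop counters account
    exactly for the intersection:
    ``n_shared == len(rows) + palindromic + info + mismatch``.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame
    n_shared: int
    n_dropped_palindromic: int
    n_dropped_info: int
    n_dropped_mismatch: int

    @property
    def n_retained(self) -> int:
        return len(self.rows)

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_dropped_palindromic
            + self.n_dropped_info
            + self.n_dropped_mismatch
        )
        if total != self.n_shared:
            raise AssertionError("drop accounting is inconsistent")


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..22 < X, Y, MT as strings)."""
    as_num = pd.to_numeric(chroms, errors="coerce")
    return pd.Series(
        [(0, float(n), "") if pd.notna(n) else (1, 0.0, c) for n, c in zip(as_num, chroms)],
        index=chroms.index,
    )


def harmonize(
    exposure: SumstatTable,
    outcome: SumstatTable,
    min_info: float = 0.9,
) -> HarmonizedPair:
    """Join two tables on shared variants and align outcome effect alleles.

    Exclusions follow fixed precedence when several rules fire:
    palindromic > low info > allele mismatch. Missing centimorgan
    positions are imputed as BP / 1e6 (1 cM per Mb) with a warning.
    """
    merged = exposure.data.merge(
        outcome.data, on="SNP", how="inner", suffixes=("_exp", "_out")
    )
    if merged.empty:
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )
    n_shared = len(merged)

    e1, e2 = merged["A1_exp"], merged["A2_exp"]
    o1, o2 = merged["A1_out"], merged["A2_out"]
    rc1 = o1.map(_COMPLEMENT)
    rc2 = o2.map(_COMPLEMENT)

    pal = (e1.map(_COMPLEMENT) == e2) | (rc1 == o2)
    low_info = (merged["INFO_exp"] < min_info) | (merged["INFO_out"] < min_info)
    same = ((o1 == e1) & (o2 == e2)) | ((rc1 == e1) & (rc2 == e2))
    swapped = ((o1 == e2) & (o2 == e1)) | ((rc1 == e2) & (rc2 == e1))
    # palindromic outcome alleles can satisfy both; precedence removes them first
    matched = same | swapped

    verdict = np.where(
        pal, "palindromic",
        np.where(low_info, "low_info", np.where(matched, "kept", "allele_mismatch")),
    )
    kept = merged[verdict == "kept"].copy()
    flip = swapped[verdict == "kept"]
    kept["BETA_out"] = np.where(flip, -kept["BETA_out"], kept["BETA_out"])
    if "EAF_out" in kept.columns:
        kept["EAF_out"] = np.where(flip, 1.0 - kept["EAF_out"], kept["EAF_out"])

    if "CM_exp" in kept.columns:
        cm = kept["CM_exp"].astype(float)
    elif "CM" in kept.columns:  # only one table carried CM
        cm = kept["CM"].astype(float)
    else:
        cm = pd.Series(np.nan, index=kept.index)
    n_missing_cm = int(cm.isna().sum())
    if n_missing_cm:
        warnings.warn(
            f"imputing {n_missing_cm} missing cM positions as BP/1e6 (1 cM per Mb)",
            stacklevel=2,
        )
        cm = cm.fillna(kept["BP_exp"] / 1e6)

    rows = pd.DataFrame(
        {
            "SNP": kept["SNP"],
            "CHR": kept["CHR_exp"],
            "BP": kept["BP_exp"],
            "CM": cm,
            "beta_exp": kept["BETA_exp"].astype(float),
            "se_exp": kept["SE_exp"].astype(float),
            "p_exp": kept["P_exp"].astype(float),
            "beta_out": kept["BETA_out"].astype(float),
            "se_out": kept["SE_out"].astype(float),
            "p_out": kept["P_out"].astype(float),
        }
    )
    if "EAF_exp" in kept.columns:
        rows["eaf_exp"] = kept["EAF_exp"].astype(float)
    rows = (
        rows.assign(_ck=_chrom_sort_key(rows["CHR"]))
        .sort_values(["_ck", "BP"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return HarmonizedPair(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        rows=rows,
        n_shared=n_shared,
        n_dropped_palindromic=int(pal.sum()),
        n_dropped_info=int((~pal & low_info).sum()),
        n_dropped_mismatch=int((~pal & ~low_info & ~matched).sum()),
    )


def write_pair(pair: HarmonizedPair, path) -> None:
    """Write a harmonized pair as TSV with a comment header carrying metadata."""
    path = Path(path)
    header = (
        f"# exposure={pair.exposure_name}\tout={pair.outcome_name}\t"
        f"n_shared={pair.n_shared}\tdropped_palindromic={pair.n_dropped_palindromic}\t"
        f"dropped_info={pair.n_dropped_info}\tdropped_mismatch={pair.n_dropped_mismatch}\n"
    )
    path.write_text(header + pair.rows.to_csv(sep="\t", index=False))


def read_pair(path) -> HarmonizedPair:
    """Read a harmonized pair written by :func:`write_pair`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SumstatFormatError(f"{path}: missing harmonized-pair metadata header")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
        )
        rows = pd.read_csv(
            fh, sep="\t", float_precision="round_trip", dtype={"SNP": str, "CHR": str}
        )
    return HarmonizedPair(
        exposure_name=meta["exposure"],
        outcome_name=meta["out"],
        rows=rows,
        n_shared=int(meta["n_shared"]),
        n_dropped_palindromic=int(meta["dropped_palindromic"]),
        n_dropped_info=int(meta["dropped_info"]),
        n_dropped_mismatch=int(meta["dropped_mismatch"]),
    )
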