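"""Instrument selection by greedy LD thinning, and variance explained.

Genetic instruments are variants genome-wide significant for the
selection trait (P < 5e-8 by default), thinned greedily by ascending
p-value until no retained pair is simultaneously within a genetic-map
window (3 cM by default) and in linkage disequilibrium above an r²
ceiling (0.05 by default). This is the standard "clumping" procedure of
GWAS follow-up pipelines; LD is supplied as a sparse pairwise table and
absent pairs are treated as unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, EmptyInstrumentError
from .sumstats import HarmonizedPair, SumstatTable, _chrom_sort_key


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    p_threshold: genome-wide significance cutoff for the selection trait.
    window_cm: genetic-map window within which LD is checked (inclusive).
    r2_max: maximum tolerated squared correlation between retained pairs.
    """

    p_threshold: float = 5e-8
    window_cm: float = 3.0
    r2_max: float = 0.05

    def __post_init__(self) -> None:
        if not (self.p_threshold > 0 and self.window_cm > 0):
            raise ConfigurationError("p_threshold and window_cm must be strictly positive")
        if not 0.0 < self.r2_max < 1.0:
            raise ConfigurationError("r2_max must lie in (0, 1)")


class LdTable:
    """Sparse symmetric map from unordered variant-id pairs to r².

    Pairs absent from the table are treated as r² = 0; LD references are
    sparse in practice and distant pairs never matter under the window
    rule.
    """

    def __init__(self) -> None:
        self._entries: dict[frozenset, float] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise ValueError(f"self-pair for variant {a!r}")
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r² must lie in [0, 1], got {r2}")
        self._entries[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        return self._entries.get(frozenset((a, b)), 0.0)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for key, r2 in self._entries.items():
            a, b = sorted(key)
            yield a, b, r2

    @classmethod
    def read(cls, path) -> "LdTable":
        """Read a tab-separated ``SNP_A SNP_B R2`` file."""
        df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.SNP_A, row.SNP_B, float(row.R2))
        return table

    def write(self, path) -> None:
        rows = sorted(self.pairs())
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class InstrumentSet:
    """The thinned, genome-wide-significant variant set used as instruments."""

    selection_trait: str
    variant_ids: list[str]
    config: SelectionConfig

    @property
    def n_instruments(self) -> int:
        return len(self.variant_ids)


def select_instruments(
    pair: HarmonizedPair,
    side: str,
    ld: LdTable,
    cfg: SelectionConfig = SelectionConfig(),
) -> InstrumentSet:
    """Greedy p-value-ordered LD thinning of genome-wide-significant variants.

    Candidates with selection-side p < ``cfg.p_threshold`` are visited by
    ascending p-value (ties broken by chromosome, position, then variant
    id, making the output deterministic); a candidate is retained iff no
    already-retained variant lies within ``cfg.window_cm`` of it (|Δcm|,
    inclusive) *and* has r² > ``cfg.r2_max`` with it. Both conditions
    must hold for a pair to conflict: distant high-LD pairs and nearby
    low-LD pairs are allowed.
    """
    if side not in ("exposure", "outcome"):
        raise ConfigurationError(f"side must be 'exposure' or 'outcome', got {side!r}")
    pcol = "p_exp" if side == "exposure" else "p_out"
    trait = pair.exposure_name if side == "exposure" else pair.outcome_name

    cand = pair.rows[pair.rows[pcol] < cfg.p_threshold]
    if cand.empty:
        raise EmptyInstrumentError(
            f"no variant reaches p < {cfg.p_threshold:g} for trait {trait!r}"
        )
    if cand["CM"].isna().any():
        raise DataError("centimorgan positions required for all candidates")
    cand = (
        cand.assign(_ck=_chrom_sort_key(cand["CHR"]))
        .sort_values([pcol, "_ck", "BP", "SNP"], kind="mergesort")
    )

    kept_ids: list[str] = []
    kept_cm: list[float] = []
    for snp, cm in zip(cand["SNP"], cand["CM"]):
        conflict = any(
            abs(cm - kcm) <= cfg.window_cm and ld.r2(snp, kid) > cfg.r2_max
            for kid, kcm in zip(kept_ids, kept_cm)
        )
        if not conflict:
            kept_ids.append(snp)
            kept_cm.append(float(cm))
    return InstrumentSet(selection_trait=trait, variant_ids=kept_ids, config=cfg)


def variance_explained(instruments: InstrumentSet, table: SumstatTable) -> float:
    """Percentage of trait variance explained by the instrument set.

    For a quantitative trait in SD units each biallelic variant with
    effect-allele frequency p and per-allele effect β contributes
    2·p·(1−p)·β² to a unit phenotypic variance. For a binary trait the
    same sum (observed scale) is rescaled to the liability scale with the
    threshold-model factor K²(1−K)² / (z²·P·(1−P)), where K is the
    population prevalence, z the standard-normal density at the (1−K)
    quantile, and P the sample case fraction.
    """
    if not instruments.variant_ids:
        return 0.0
    if "EAF" not in table.data.columns:
        raise DataError(
            f"effect-allele frequencies required: missing for all of "
            f"{', '.join(instruments.variant_ids[:5])}..."
        )
    sub = table.data.set_index("SNP").reindex(instruments.variant_ids)
    missing = sub.index[sub["BETA"].isna() | sub["EAF"].isna()].tolist()
    if missing:
        raise DataError(f"missing eaf or effect for variants: {', '.join(map(str, missing))}")
    p = sub["EAF"].to_numpy(float)
    beta = sub["BETA"].to_numpy(float)
    observed = float(np.sum(2.0 * p * (1.0 - p) * beta**2))
    if table.trait_type == "binary":
        if table.prevalence is None:
            raise ConfigurationError(
                f"binary trait {table.trait_name!r} requires a prevalence"
            )
        k = table.prevalence
        case_frac = table.case_fraction if table.case_fraction is not None else k
        z = stats.norm.pdf(stats.norm.ppf(1.0 - k))
        observed *= k**2 * (1.0 - k) ** 2 / (z**2 * case_frac * (1.0 - case_frac))
    return 100.0 * observed
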