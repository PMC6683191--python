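"""Synthetic paired GWAS summary statistics with known causal ground truth.

Summary statistics are simulated directly at the estimate level: each
variant has a true per-allele exposure effect and a true outcome effect
(theta times the exposure effect plus any direct, i.e. pleiotropic,
effect), and the published estimates are those truths plus independent
normal noise with the sampling SE implied by allele frequency and GWAS
sample size. This gives exact control over standard errors, instrument
strength and pleiotropy at negligible cost, which is what pipeline-level
statistical tests need; it deliberately does not model genotypes,
realistic LD decay or population structure.

The defaults emulate the data regime of a large biobank anthropometric
GWAS (quantitative exposure, n ≈ 330,000, effects in phenotype SDs) run
against a major-depression case-control GWAS (binary outcome on the
log-odds scale, n ≈ 173,000, 35% cases, population prevalence 15%),
including palindromic variants, sub-threshold imputation info scores,
and LD blocks laid out on a centimorgan map.

Directional pleiotropy is applied relative to the exposure-increasing
allele: a positive ``pleiotropy_mean`` pushes outcome effects up for
alleles that raise the exposure, which is what makes the pleiotropy
"directional" for ratio-based estimators regardless of arbitrary allele
labelling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import LdTable
from .sumstats import SumstatTable, write_sumstats

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_CHOICES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generative model for one exposure/outcome pair.

    Instrument strength is parameterized on the z-score scale:
    causal exposure effects have |true beta| ≈ (instrument_z_mean ±
    instrument_z_sd) × sampling SE at ``n_exposure``, so instruments
    reach genome-wide significance with high probability, as hits from a
    330,000-sample GWAS do.
    """

    n_snps: int = 1000
    n_causal: int = 150
    theta: float = 0.2
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 330_000
    n_outcome: int = 173_000
    outcome_type: str = "binary"  # binary | quantitative
    case_fraction: float = 0.35
    prevalence: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 150
    block_r2: float = 0.8
    cm_span: float = 4.0
    palindromic_frac: float = 0.10
    low_info_frac: float = 0.05
    instrument_z_mean: float = 10.0
    instrument_z_sd: float = 2.0
    seed: int = 0
    exposure_name: str = "exposure"
    outcome_name: str = "depression"

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ConfigurationError("n_causal must not exceed n_snps")
        for name in ("pleiotropy_frac", "palindromic_frac", "low_info_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.block_r2 < 1.0:
            raise ConfigurationError("block_r2 must lie in [0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if self.outcome_type not in ("binary", "quantitative"):
            raise ConfigurationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.n_blocks < 1 or self.n_snps < 1:
            raise ConfigurationError("n_blocks and n_snps must be >= 1")


@dataclass
class SimTruth:
    """Per-variant ground truth: the ledger parameter-recovery tests read.

    ``table`` columns: SNP, block, beta_x_true, direct_effect, causal,
    pleiotropic. The invariant ``beta_y_true = theta * beta_x_true +
    direct_effect`` holds exactly per variant.
    """

    theta: float
    table: pd.DataFrame

    @property
    def beta_y_true(self) -> np.ndarray:
        return self.theta * self.table["beta_x_true"].to_numpy() + self.table[
            "direct_effect"
        ].to_numpy()


def _quant_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _binary_se(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    v = case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * v)


def simulate_pair(cfg: SimConfig) -> tuple[SumstatTable, SumstatTable, LdTable, SimTruth]:
    """Simulate an exposure table, an outcome table, an LD table and the truth.

    Block b of the centimorgan map starts at b·(cm_span + 1), so SNPs in
    different blocks are always more than ``cm_span`` apart while SNPs
    within a block sit inside a 1 cM stretch; every within-block pair is
    listed in the LD table at ``block_r2``. The outcome table's allele
    representation is randomly strand-flipped and allele-swapped per
    variant so harmonization is exercised on every simulated pair.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps

    block = np.sort(rng.integers(0, cfg.n_blocks, size=m))
    cm = block * (cfg.cm_span + 1.0) + rng.uniform(0.0, 1.0, size=m)
    order = np.argsort(cm, kind="stable")
    cm, block = cm[order], block[order]
    bp = np.round(cm * 1e6).astype(int) + 1
    bp = np.maximum.accumulate(bp + np.arange(m))  # strictly increasing
    snp = np.array([f"rs{i + 1:06d}" for i in range(m)])

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    se_x = _quant_se(maf, cfg.n_exposure)
    if cfg.outcome_type == "binary":
        se_y = _binary_se(maf, cfg.n_outcome, cfg.case_fraction)
    else:
        se_y = _quant_se(maf, cfg.n_outcome)

    causal_idx = rng.choice(m, size=cfg.n_causal, replace=False)
    causal = np.zeros(m, dtype=bool)
    causal[causal_idx] = True
    z = rng.normal(cfg.instrument_z_mean, cfg.instrument_z_sd, size=cfg.n_causal)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_causal)
    beta_x_true = np.zeros(m)
    beta_x_true[causal_idx] = sign * np.abs(z) * se_x[causal_idx]

    pleiotropic = np.zeros(m, dtype=bool)
    n_pleio = int(round(cfg.pleiotropy_frac * cfg.n_causal))
    if n_pleio:
        pleio_idx = rng.choice(causal_idx, size=n_pleio, replace=False)
        pleiotropic[pleio_idx] = True
    direct = np.zeros(m)
    if n_pleio:
        raw = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)
        # aligned with the exposure-increasing allele
        direct[pleiotropic] = np.sign(beta_x_true[pleiotropic]) * raw
    beta_y_true = cfg.theta * beta_x_true + direct

    beta_x_hat = beta_x_true + se_x * rng.standard_normal(m)
    beta_y_hat = beta_y_true + se_y * rng.standard_normal(m)
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x_hat / se_x))
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y_hat / se_y))
    p_x = np.maximum(p_x, 1e-300)
    p_y = np.maximum(p_y, 1e-300)

    info_x = np.ones(m)
    info_y = np.ones(m)
    n_low = int(round(cfg.low_info_frac * m))
    if n_low:
        low_idx = rng.choice(m, size=n_low, replace=False)
        low_side = rng.random(n_low) < 0.5
        info_x[low_idx[low_side]] = rng.uniform(0.5, 0.899, size=int(low_side.sum()))
        info_y[low_idx[~low_side]] = rng.uniform(0.5, 0.899, size=int((~low_side).sum()))

    n_pal = int(round(cfg.palindromic_frac * m))
    pal = np.zeros(m, dtype=bool)
    if n_pal:
        pal[rng.choice(m, size=n_pal, replace=False)] = True
    pair_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    pal_choice = rng.integers(0, len(_PALINDROMIC_CHOICES), size=m)
    a1 = np.where(
        pal,
        [_PALINDROMIC_CHOICES[i][0] for i in pal_choice],
        [_NONPALINDROMIC_PAIRS[i][0] for i in pair_choice],
    )
    a2 = np.where(
        pal,
        [_PALINDROMIC_CHOICES[i][1] for i in pal_choice],
        [_NONPALINDROMIC_PAIRS[i][1] for i in pair_choice],
    )

    chrom = np.full(m, "1")
    exposure_df = pd.DataFrame(
        {
            "SNP": snp, "CHR": chrom, "BP": bp, "A1": a1, "A2": a2,
            "BETA": beta_x_hat, "SE": se_x, "P": p_x, "INFO": info_x,
            "N": cfg.n_exposure, "CM": cm, "EAF": maf,
        }
    )

    # outcome representation: random allele swap and random strand flip
    swap = rng.random(m) < 0.5
    flip = rng.random(m) < 0.3
    o1 = np.where(swap, a2, a1)
    o2 = np.where(swap, a1, a2)
    o1 = np.where(flip, [_RC[x] for x in o1], o1)
    o2 = np.where(flip, [_RC[x] for x in o2], o2)
    beta_y_stored = np.where(swap, -beta_y_hat, beta_y_hat)
    eaf_y_stored = np.where(swap, 1.0 - maf, maf)
    outcome_df = pd.DataFrame(
        {
            "SNP": snp, "CHR": chrom, "BP": bp, "A1": o1, "A2": o2,
            "BETA": beta_y_stored, "SE": se_y, "P": p_y, "INFO": info_y,
            "N": cfg.n_outcome, "CM": cm, "EAF": eaf_y_stored,
        }
    )

    exposure = SumstatTable(cfg.exposure_name, "quantitative", exposure_df)
    if cfg.outcome_type == "binary":
        outcome = SumstatTable(
            cfg.outcome_name, "binary", outcome_df,
            prevalence=cfg.prevalence, case_fraction=cfg.case_fraction,
        )
    else:
        outcome = SumstatTable(cfg.outcome_name, "quantitative", outcome_df)

    ld = LdTable()
    for b in range(cfg.n_blocks):
        members = snp[block == b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ld.add(members[i], members[j], cfg.block_r2)

    truth = SimTruth(
        theta=cfg.theta,
        table=pd.DataFrame(
            {
                "SNP": snp, "block": block, "beta_x_true": beta_x_true,
                "direct_effect": direct, "causal": causal, "pleiotropic": pleiotropic,
            }
        ),
    )
    return exposure, outcome, ld, truth


# ---------------------------------------------------------------------------
# canonical fixture suite

FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "clean": SimConfig(
        n_snps=300, n_causal=60, n_blocks=60, theta=0.2,
        palindromic_frac=0.0, low_info_frac=0.0, seed=101,
    ),
    "contaminated": SimConfig(
        n_snps=300, n_causal=60, n_blocks=60, theta=0.2,
        palindromic_frac=0.2, low_info_frac=0.1, seed=102,
    ),
    "directional_pleiotropy": SimConfig(
        n_snps=300, n_causal=60, n_blocks=60, theta=0.2,
        pleiotropy_frac=0.4, pleiotropy_mean=0.03, pleiotropy_sd=0.005,
        palindromic_frac=0.0, low_info_frac=0.0, seed=103,
    ),
    "null": SimConfig(
        n_snps=300, n_causal=60, n_blocks=60, theta=0.0,
        palindromic_frac=0.0, low_info_frac=0.0, seed=104,
    ),
}


def make_fixture_suite(out_dir, seed: int | None = None) -> list[Path]:
    """Write the four canonical fixture pairs with their truth ledgers.

    Each scenario yields ``<name>.exposure.tsv``, ``<name>.outcome.tsv``,
    ``<name>.ld.tsv``, ``<name>.truth.tsv`` and ``<name>.meta.json``
    (theta and the generating configuration). With ``seed`` given, every
    scenario's configured seed is offset by it; identical arguments give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, cfg in FIXTURE_CONFIGS.items():
        if seed is not None:
            cfg = SimConfig(**{**asdict(cfg), "seed": cfg.seed + seed})
        exposure, outcome, ld, truth = simulate_pair(cfg)
        paths = {
            "exposure": out_dir / f"{name}.exposure.tsv",
            "outcome": out_dir / f"{name}.outcome.tsv",
            "ld": out_dir / f"{name}.ld.tsv",
            "truth": out_dir / f"{name}.truth.tsv",
            "meta": out_dir / f"{name}.meta.json",
        }
        write_sumstats(exposure, paths["exposure"])
        write_sumstats(outcome, paths["outcome"])
        ld.write(paths["ld"])
        paths["truth"].write_text(truth.table.to_csv(sep="\t", index=False))
        meta = {"theta": cfg.theta, "config": asdict(cfg)}
        paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        written.extend(paths.values())
    return written
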