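"""Two-sample Mendelian randomization estimators.

Given per-variant exposure effects bx (SD units) and outcome effects by
(log-odds or SD units) with standard errors, four analyses are provided:

* ``ivw`` — inverse-variance-weighted regression of by on bx through the
  origin, weights 1/sy²; the workhorse estimator.
* ``ivw_excluding_pleiotropic`` — the same after removing variants whose
  per-variant Cochran-Q contribution is Bonferroni-significant.
* ``weighted_median`` — the interpolated weighted median of per-variant
  Wald ratios; consistent when at least half the weight comes from valid
  instruments. Its SE comes from a parametric bootstrap.
* ``egger`` — weighted regression *with* an intercept after orienting all
  variants to positive exposure effect; a nonzero intercept indicates
  directional pleiotropy and the slope is a pleiotropy-adjusted estimate.

Standard errors for the regression estimators use a multiplicative
random-effects model: the fixed-effect SE is inflated by
max(1, sqrt(Q / df)), so under-dispersion is never rewarded. A
fixed-effect mode is exposed via ``random_effects=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedPair


@dataclass
class MrInput:
    """Parallel per-variant effect vectors for one exposure/outcome pair."""

    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        lengths = {len(self.bx), len(self.sx), len(self.by), len(self.sy), len(self.variant_ids)}
        if lengths != {len(self.bx)} or len(self.bx) < 1:
            raise ValueError("bx, sx, by, sy, variant_ids must have equal length >= 1")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("all standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.bx)

    @classmethod
    def from_pair(cls, pair: HarmonizedPair, variant_ids: Sequence[str]) -> "MrInput":
        """Restrict a harmonized pair to the given instruments."""
        sub = pair.rows.set_index("SNP").loc[list(variant_ids)]
        return cls(
            bx=sub["beta_exp"].to_numpy(float),
            sx=sub["se_exp"].to_numpy(float),
            by=sub["beta_out"].to_numpy(float),
            sy=sub["se_out"].to_numpy(float),
            variant_ids=list(variant_ids),
        )

    def subset(self, keep: Sequence[str]) -> "MrInput":
        idx = [self.variant_ids.index(v) for v in keep]
        return MrInput(
            self.bx[idx], self.sx[idx], self.by[idx], self.sy[idx], list(keep)
        )


@dataclass
class MrResult:
    """One estimator's causal-slope estimate with its uncertainty.

    ``slope`` is the change in outcome units per SD of exposure. The
    Egger fields are populated only for ``method == "egger"``;
    ``excluded_ids`` only for ``ivw_excl``; ``seed`` only for the
    bootstrap-based ``median``.
    """

    method: str
    slope: float
    slope_se: float
    slope_p: float
    n_snps_used: int
    q_statistic: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    excluded_ids: list[str] = field(default_factory=list)
    seed: Optional[int] = None


def _two_sided_p(estimate: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def ratio_estimates(inp: MrInput) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios by/bx and their first-order SEs sy/|bx|."""
    zero = np.flatnonzero(inp.bx == 0.0)
    if zero.size:
        names = ", ".join(inp.variant_ids[i] for i in zero)
        raise DegenerateInstrumentError(f"zero exposure effect for: {names}")
    return inp.by / inp.bx, inp.sy / np.abs(inp.bx)


def ivw(inp: MrInput, random_effects: bool = True) -> MrResult:
    """Inverse-variance-weighted regression through the origin.

    slope = Σ wⱼ bxⱼ byⱼ / Σ wⱼ bxⱼ² with wⱼ = 1/syⱼ²;
    Q = Σ wⱼ (byⱼ − slope·bxⱼ)² is Cochran's heterogeneity statistic.
    """
    j = len(inp)
    if j < 2:
        raise InsufficientInstrumentsError(f"ivw requires >= 2 instruments, got {j}")
    w = 1.0 / inp.sy**2
    sxx = float(np.sum(w * inp.bx**2))
    slope = float(np.sum(w * inp.bx * inp.by)) / sxx
    q = float(np.sum(w * (inp.by - slope * inp.bx) ** 2))
    se = np.sqrt(1.0 / sxx)
    if random_effects:
        se *= max(1.0, np.sqrt(q / (j - 1)))
    return MrResult(
        method="ivw",
        slope=slope,
        slope_se=float(se),
        slope_p=_two_sided_p(slope, se),
        n_snps_used=j,
        q_statistic=q,
    )


def egger(inp: MrInput, random_effects: bool = True) -> MrResult:
    """Weighted regression with intercept after orienting exposure effects > 0.

    Each variant is first re-signed so bxⱼ > 0 (byⱼ flipped with it) —
    without a fixed orientation the intercept has no meaning. The slope
    is robust to directional pleiotropy under the assumption that
    instrument strength is independent of direct effects.
    """
    j = len(inp)
    if j < 3:
        raise InsufficientInstrumentsError(f"egger requires >= 3 instruments, got {j}")
    orient = np.where(inp.bx < 0, -1.0, 1.0)
    bx = inp.bx * orient
    by = inp.by * orient
    w = 1.0 / inp.sy**2

    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx**2))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    mult = max(1.0, np.sqrt(q / (j - 2))) if random_effects else 1.0
    slope_se = np.sqrt(sw / det) * mult
    intercept_se = np.sqrt(swxx / det) * mult
    return MrResult(
        method="egger",
        slope=float(slope),
        slope_se=float(slope_se),
        slope_p=_two_sided_p(slope, slope_se),
        n_snps_used=j,
        q_statistic=q,
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        intercept_p=_two_sided_p(intercept, intercept_se),
    )


def _interpolated_weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """The ratio at which cumulative weight minus half the own weight crosses 1/2."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - w / 2.0
    if p[0] >= 0.5:
        return float(r[0])
    k = int(np.searchsorted(p, 0.5))  # first index with p[k] >= 0.5; k >= 1 here
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized interpolated weighted median along the last axis."""
    order = np.argsort(ratios, axis=-1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / np.sum(w, axis=-1, keepdims=True)
    p = np.cumsum(w, axis=-1) - w / 2.0
    k = np.argmax(p >= 0.5, axis=-1)
    k0 = np.maximum(k - 1, 0)
    rows = np.arange(r.shape[0])
    rk, rk0 = r[rows, k], r[rows, k0]
    pk, pk0 = p[rows, k], p[rows, k0]
    with np.errstate(invalid="ignore", divide="ignore"):
        interp = rk0 + (rk - rk0) * (0.5 - pk0) / (pk - pk0)
    return np.where(k == 0, r[rows, 0], interp)


def weighted_median(inp: MrInput, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Interpolated weighted-median of Wald ratios, bootstrap SE.

    Weights are inverse squared first-order ratio SEs, normalized to sum
    to one. The SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples (bxⱼ ~ N(bxⱼ, sxⱼ²), byⱼ ~ N(byⱼ,
    syⱼ²), weights recomputed per replicate); a fixed seed makes the
    result reproducible.
    """
    j = len(inp)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 instruments, got {j}")
    ratios, ratio_ses = ratio_estimates(inp)
    estimate = _interpolated_weighted_median(ratios, 1.0 / ratio_ses**2)

    rng = np.random.default_rng(seed)
    bxs = inp.bx + inp.sx * rng.standard_normal((n_boot, j))
    bys = inp.by + inp.sy * rng.standard_normal((n_boot, j))
    bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
    boot_ratios = bys / bxs
    boot_weights = (np.abs(bxs) / inp.sy) ** 2
    boot = _weighted_median_rows(boot_ratios, boot_weights)
    se = float(np.std(boot, ddof=1))
    # degenerate inputs (all ratios identical) give se = 0; report p = 1 then
    p = _two_sided_p(estimate, se) if se > 0 else 1.0
    return MrResult(
        method="median",
        slope=float(estimate),
        slope_se=se,
        slope_p=p,
        n_snps_used=j,
        q_statistic=float("nan"),
        seed=seed,
    )


def flag_pleiotropic(inp: MrInput, alpha: float = 0.05) -> list[str]:
    """Variants whose Cochran-Q contribution is Bonferroni-significant.

    The IVW fit on all variants yields per-variant contributions
    Qⱼ = wⱼ (byⱼ − slope·bxⱼ)², referred to χ²₁; variant j is flagged iff
    its tail probability falls below alpha/N with N the instrument count.
    Returned sorted by variant id.
    """
    if len(inp) < 3:
        raise InsufficientInstrumentsError(
            f"pleiotropy screening requires >= 3 instruments, got {len(inp)}"
        )
    fit = ivw(inp)
    w = 1.0 / inp.sy**2
    q_j = w * (inp.by - fit.slope * inp.bx) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    threshold = alpha / len(inp)
    return sorted(v for v, p in zip(inp.variant_ids, p_j) if p < threshold)


def ivw_excluding_pleiotropic(inp: MrInput, alpha: float = 0.05) -> MrResult:
    """IVW on the complement of the pleiotropy-flagged variants."""
    excluded = flag_pleiotropic(inp, alpha=alpha)
    keep = [v for v in inp.variant_ids if v not in set(excluded)]
    if len(keep) < 2:
        raise InsufficientInstrumentsError(
            f"only {len(keep)} instruments remain after pleiotropy exclusion"
        )
    result = ivw(inp.subset(keep))
    result.method = "ivw_excl"
    result.excluded_ids = excluded
    return result
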