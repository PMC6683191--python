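"""Bidirectional multi-trait MR battery with Bonferroni control.

Runs the full pipeline — harmonize, select instruments on the exposure
side, apply all four estimators — for each trait in each causal
direction, and renders a per-trait report. Each cell's significance flag
is attached to the all-variant IVW slope only, against the Bonferroni
threshold alpha / n_tests; the sensitivity analyses (pleiotropy-excluded
IVW, weighted median, Egger) are reported alongside but never drive the
flag. ``n_tests`` is a configuration constant rather than the number of
cells actually run, so partial runs keep the same threshold as a full
battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from scipy import stats

from .errors import ConfigurationError, MrBatteryError
from .estimators import (
    MrInput,
    MrResult,
    egger,
    ivw,
    ivw_excluding_pleiotropic,
    weighted_median,
)
from .instruments import LdTable, SelectionConfig, select_instruments
from .sumstats import SumstatTable, harmonize

METHODS = ("ivw", "ivw_excl", "median", "egger")


@dataclass(frozen=True)
class BatteryConfig:
    """Battery-wide settings; defaults give a 42-test Bonferroni design."""

    alpha: float = 0.05
    n_tests: int = 42
    directions: str = "both"  # both | forward | reverse
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_boot: int = 1000
    seed: int = 0
    min_info: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1")
        if self.directions not in ("both", "forward", "reverse"):
            raise ConfigurationError(f"unknown directions {self.directions!r}")


def critical_z(alpha: float, n_tests: int) -> float:
    """|slope/se| threshold equivalent to the two-sided Bonferroni p rule.

    The standard-normal quantile at 1 − (alpha/n_tests)/2: a slope is
    Bonferroni-significant iff it lies at least this many SEs from zero.
    """
    return float(stats.norm.isf(alpha / n_tests / 2.0))


@dataclass
class BatteryCell:
    """One exposure → outcome analysis: four estimates plus a significance flag."""

    exposure: str
    outcome: str
    direction: str  # forward | reverse
    results: dict[str, MrResult] = field(default_factory=dict)
    n_instruments: int = 0
    significant: bool = False
    error: Optional[str] = None


@dataclass
class BatteryReport:
    """All cells of a battery run plus the configuration that produced them."""

    cells: list[BatteryCell]
    config: BatteryConfig

    def cell(self, exposure: str, outcome: str) -> BatteryCell:
        for c in self.cells:
            if c.exposure == exposure and c.outcome == outcome:
                return c
        raise KeyError(f"no cell {exposure!r} -> {outcome!r}")


def run_direction(
    exposure: SumstatTable,
    outcome: SumstatTable,
    ld: LdTable,
    cfg: BatteryConfig,
    direction: str = "forward",
) -> BatteryCell:
    """Run one causal direction: instruments from the exposure, all four estimators.

    Selection always operates on the exposure side of the harmonized
    pair; swapping the roles of the two tables therefore changes the
    instrument set, reflecting the asymmetry of the causal question.
    """
    try:
        pair = harmonize(exposure, outcome, min_info=cfg.min_info)
        instruments = select_instruments(pair, "exposure", ld, cfg.selection)
        inp = MrInput.from_pair(pair, instruments.variant_ids)
        results = {
            "ivw": ivw(inp),
            "ivw_excl": ivw_excluding_pleiotropic(inp, alpha=cfg.alpha),
            "median": weighted_median(inp, n_boot=cfg.n_boot, seed=cfg.seed),
            "egger": egger(inp),
        }
    except MrBatteryError as exc:
        raise type(exc)(f"[{direction}: {exposure.trait_name} -> {outcome.trait_name}] {exc}") from exc
    return BatteryCell(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        direction=direction,
        results=results,
        n_instruments=instruments.n_instruments,
        significant=bool(results["ivw"].slope_p < cfg.alpha / cfg.n_tests),
    )


def run_battery(
    traits: list[SumstatTable],
    depression_outcome: SumstatTable,
    depression_exposure: SumstatTable,
    ld: LdTable,
    cfg: BatteryConfig = BatteryConfig(),
) -> BatteryReport:
    """Run every trait in the requested directions against the focal outcome.

    Two focal-trait tables are required because the two directions have
    different data needs: the forward direction (trait → outcome) needs
    genome-wide outcome results at the trait's instruments
    (``depression_outcome``), while the reverse direction (outcome →
    trait) needs a table dense enough at its own top hits to source
    instruments (``depression_exposure``). Per-cell failures are recorded
    in the report rather than aborting the battery.
    """
    cells: list[BatteryCell] = []
    for trait in traits:
        if cfg.directions in ("both", "forward"):
            cells.append(_run_cell(trait, depression_outcome, ld, cfg, "forward"))
        if cfg.directions in ("both", "reverse"):
            cells.append(_run_cell(depression_exposure, trait, ld, cfg, "reverse"))
    return BatteryReport(cells=cells, config=cfg)


def _run_cell(exposure, outcome, ld, cfg, direction) -> BatteryCell:
    try:
        return run_direction(exposure, outcome, ld, cfg, direction)
    except MrBatteryError as exc:
        return BatteryCell(
            exposure=exposure.trait_name,
            outcome=outcome.trait_name,
            direction=direction,
            error=str(exc),
        )


# ---------------------------------------------------------------------------
# rendering


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.6g}"


def _cell_fields(cell: Optional[BatteryCell]) -> list[str]:
    """The 15 per-direction report columns for one cell (NA-filled on failure)."""
    if cell is None or cell.error is not None:
        return ["NA"] * (3 * len(METHODS) + 2) + [""]
    out: list[str] = []
    for method in METHODS:
        r = cell.results[method]
        out += [_fmt(r.slope), _fmt(r.slope_se), _fmt(r.slope_p)]
    out += [_fmt(cell.results["egger"].intercept_p), str(cell.n_instruments)]
    out.append("*" if cell.significant else "")
    return out


def render_report(report: BatteryReport, path) -> None:
    """Write the battery as a TSV: one row per trait, forward then reverse columns.

    Per direction the columns are slope/SE/p for each of the four
    methods, the Egger intercept p, the instrument count, and a ``*``
    significance mark (all-variant IVW against alpha/n_tests); a final
    ``notes`` column surfaces per-cell failures. Rendering is a pure
    function of the report: re-rendering an unchanged report reproduces
    identical bytes.
    """
    forward = {c.exposure: c for c in report.cells if c.direction == "forward"}
    reverse = {c.outcome: c for c in report.cells if c.direction == "reverse"}
    traits = list(dict.fromkeys(list(forward) + list(reverse)))

    sub = [f"{m}_{f}" for m in METHODS for f in ("slope", "se", "p")]
    sub += ["egger_intercept_p", "n_snps", "significant"]
    header = ["trait"]
    for prefix in ("fwd", "rev"):
        header += [f"{prefix}_{c}" for c in sub]
    header.append("notes")

    lines = ["\t".join(header)]
    for trait in traits:
        fcell = forward.get(trait)
        rcell = reverse.get(trait)
        notes = "; ".join(
            c.error for c in (fcell, rcell) if c is not None and c.error
        )
        row = [trait] + _cell_fields(fcell) + _cell_fields(rcell) + [notes]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
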