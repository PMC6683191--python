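"""Exception hierarchy for the mrbattery pipeline."""


class MrBatteryError(Exception):
    """Base class for all pipeline errors."""


class SumstatFormatError(MrBatteryError):
    """A summary-statistic file is structurally malformed (missing columns, bad header)."""


class SumstatValidationError(MrBatteryError):
    """One or more rows violate per-record invariants.

    Carries a list of (row_index, message) pairs so callers can report
    exactly which input lines were rejected.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems[:20])
        extra = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{extra}")


class ConfigurationError(MrBatteryError):
    """Invalid or incomplete configuration (e.g. binary trait without prevalence)."""


class EmptyIntersectionError(MrBatteryError):
    """Exposure and outcome tables share no variants."""


class EmptyInstrumentError(MrBatteryError):
    """No variant passes the genome-wide significance threshold for the selection trait."""


class InsufficientInstrumentsError(MrBatteryError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(MrBatteryError):
    """An instrument has a zero exposure effect, so its Wald ratio is undefined."""


class DataError(MrBatteryError):
    """Required per-variant data (e.g. effect-allele frequency) is missing."""
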