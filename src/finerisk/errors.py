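"""Exception hierarchy for the finerisk pipeline."""


class FineriskError(Exception):
    """Base class for all finerisk errors."""


class ConfigurationError(FineriskError):
    """A simulation or pipeline configuration field is invalid."""


class SimulationError(FineriskError):
    """Requested cohort could not be sampled from the simulated base population."""


class MatchingError(FineriskError):
    """Age-matched case-control sampling failed for one or more cases."""

    def __init__(self, message, unmatched=()):
        super().__init__(message)
        self.unmatched = list(unmatched)


class ParseError(FineriskError):
    """A file violated its schema; carries the offending line number when known."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class CollinearityError(FineriskError):
    """Summary-statistic joint system is singular or above the r^2 guard."""

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class PanelMismatchError(FineriskError):
    """Weight-panel SNVs missing from (or allele-incompatible with) the dosage data."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class ImputationError(FineriskError):
    """Covariate missingness outside the supported pattern, or no donors to fit on."""


class EvaluationError(FineriskError):
    """Degenerate input to a model-evaluation routine (single class, zero variance, separation)."""


class RateCoverageError(FineriskError):
    """Rate table does not cover the requested age span."""
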