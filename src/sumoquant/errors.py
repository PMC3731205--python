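"""Exception hierarchy for the sumoquant pipeline."""


class SumoQuantError(Exception):
    """Base class for all sumoquant errors."""


class ConfigError(SumoQuantError):
    """Invalid generator or run configuration."""


class DesignError(SumoQuantError):
    """Invalid or unknown experiment design / genotype label."""


class SchemaError(SumoQuantError):
    """A table is missing required columns or has an unreadable layout."""


class ParameterError(SumoQuantError):
    """Invalid numerical parameter (rates, folds, intensities)."""


class UnquantifiablePeptideError(SumoQuantError):
    """Both SILAC channels are empty; no ratio can be formed."""


class BelowDetectionError(SumoQuantError):
    """All fluctuation-assay cultures had zero mutants.

    Carries ``upper_bound``, the rate consistent with observing no mutants
    in any of the ``n`` parallel cultures.
    """

    def __init__(self, message: str, upper_bound: float):
        super().__init__(message)
        self.upper_bound = upper_bound


class PackagingError(SumoQuantError):
    """A packaged data fixture is missing or corrupt."""
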