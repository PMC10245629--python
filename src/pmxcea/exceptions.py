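"""Exception hierarchy for the pmxcea pipeline.

Exit-code mapping in the CLI: ConfigurationError -> 1, DataError -> 2.
"""


class PMXCEAError(Exception):
    """Base class for all pmxcea errors."""


class ConfigurationError(PMXCEAError):
    """Invalid user-supplied configuration (bad prevalence, k < 1, rate <= 0, ...)."""


class DataError(PMXCEAError):
    """Malformed or inconsistent input data."""


class LifeTableFormatError(DataError):
    """Life-table file fails validation (missing columns, duplicates, negative values)."""


class LifeTableLookupError(DataError):
    """Requested sex stratum absent from the life table and no fallback available."""


class SeparationError(DataError):
    """Perfect separation in the propensity logistic fit; coefficients diverge."""


class UndefinedICERError(PMXCEAError):
    """ICER requested with a zero QALY difference."""


class StratumError(PMXCEAError):
    """A required analysis stratum has an empty arm."""
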