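"""Exception hierarchy shared across the package."""


class SemCohortError(Exception):
    """Base class for all package errors."""


class ModelSpecError(SemCohortError):
    """Malformed or inconsistent model description."""


class ModelStructureError(SemCohortError):
    """Structurally invalid model at evaluation time (e.g. singular I - B)."""


class NumericDomainError(SemCohortError):
    """Numeric-domain violation (non-PD matrix, df <= 0, ...)."""


class DataError(SemCohortError):
    """Invalid or incomplete tabular input."""


class ConfigError(SemCohortError):
    """Invalid generator / pipeline configuration."""
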