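"""Exception hierarchy for the watercore pipeline."""


class WatercoreError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(WatercoreError):
    """Invalid configuration values (grids, ranges, counts, orientations)."""


class DegenerateInputError(WatercoreError):
    """Input data that violates a stage's precondition (too few scans, one class, ...)."""


class SingularSystemError(WatercoreError):
    """The LS-SVM dual linear system could not be solved."""
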