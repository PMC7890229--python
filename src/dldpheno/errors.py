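"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by click
(exit 2), :class:`DataValidationError` maps to exit 3, anything else
to exit 4.
"""


class DldPhenoError(Exception):
    """Base class for all package errors."""


class InvalidCodeError(DldPhenoError):
    """An ICD code string that cannot be normalized (empty / whitespace)."""


class DataValidationError(DldPhenoError):
    """Input data violates a documented contract (bad column, bad label, ...)."""


class ContractError(DldPhenoError):
    """A caller violated an operation precondition (e.g. no LD code present)."""


class UndefinedMetricError(DldPhenoError):
    """A validation metric has a zero denominator; reported as N/A, never 0."""
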