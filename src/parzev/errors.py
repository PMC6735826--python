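"""Exception hierarchy.

Errors map onto CLI exit codes: :class:`InputError` (and subclasses) exit
with code 1, anything else with code 2.
"""


class ParzevError(Exception):
    """Base class for all package errors."""


class InputError(ParzevError):
    """Malformed, inconsistent, or missing user input."""


class ConfigurationError(InputError):
    """Invalid simulation or pipeline configuration."""


class InsufficientDataError(InputError):
    """Not enough data points to run the requested inference."""


class UndefinedValueError(ParzevError):
    """A statistic is undefined for the given input (e.g. no synonymous codons)."""
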