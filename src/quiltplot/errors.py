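"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration/validation problems are
user errors (exit 1); parse, contract and external-tool failures are
runtime errors (exit 2).
"""


class QuiltPlotError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuiltPlotError):
    """Bad flags, bad schema, or an invalid style parameter combination."""


class InputValidationError(QuiltPlotError):
    """Input data that parses but violates a stated invariant."""


class ParseError(QuiltPlotError):
    """A malformed alignment or annotation file."""


class ContractError(QuiltPlotError):
    """An API precondition violated by the caller (internal misuse)."""


class AlignerError(QuiltPlotError):
    """An external alignment tool failed or is unavailable."""
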