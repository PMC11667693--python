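"""Exception hierarchy shared across the package.

All errors raised by phenorag derive from :class:`PhenoRagError` so callers
can catch package failures with a single except clause. The CLI maps
``ConfigurationError``/``ValidationError`` to exit code 2 and
``FormatError``/``InputError`` to exit code 3.
"""


class PhenoRagError(Exception):
    """Base class for all phenorag errors."""


class ValidationError(PhenoRagError):
    """An argument or data structure violates a documented precondition."""


class ConfigurationError(PhenoRagError):
    """Backend, store, or run configuration is inconsistent or unknown."""


class FormatError(PhenoRagError):
    """A file or raw text does not conform to the expected dialect."""


class InputError(PhenoRagError):
    """A required input file is missing or unreadable."""


class ParseError(FormatError):
    """A completion or record could not be parsed; carries the raw text."""

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw
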