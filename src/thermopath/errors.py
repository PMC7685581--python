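"""Exception hierarchy shared across the package.

Every error raised by thermopath derives from :class:`ThermopathError`
so callers can catch the whole family with one clause. The subclasses
mirror the failure modes of a tabular pipeline: malformed files,
semantically invalid data, bad configuration, and inputs that are
well-formed but degenerate (e.g. an all-zero sample).
"""


class ThermopathError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ThermopathError):
    """A file could not be parsed (ragged rows, bad tokens, duplicate ids)."""


class ValidationError(ThermopathError):
    """Parsed data violates a domain invariant (negative abundance, empty pathway)."""


class ConfigurationError(ThermopathError):
    """Inconsistent or incomplete run configuration."""


class DegenerateInputError(ThermopathError):
    """Input is structurally valid but has no defined result (all-zero sample)."""


class SampleLookupError(ThermopathError, KeyError):
    """A referenced sample id does not exist in the table."""
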