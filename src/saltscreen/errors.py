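"""Exception hierarchy for the screening pipeline.

Every error raised on bad user input derives from :class:`SaltScreenError`
so the CLI can map validation failures to exit code 2.
"""


class SaltScreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(SaltScreenError):
    """A table is missing required columns or has the wrong header."""


class IntegrityError(SaltScreenError):
    """Duplicate keys or referential problems inside a table."""


class ValidationError(SaltScreenError):
    """Values violate a documented invariant (negative, non-finite, ...)."""


class MissingControlError(SaltScreenError):
    """A stressed (genotype, trait) has no 0 mM/L control measurements."""


class UndefinedIndexError(SaltScreenError):
    """Undefined (zero-control) index rows reached a stage whose policy is 'fail'."""


class DegenerateInputError(SaltScreenError):
    """Input degenerate for the requested operation (e.g. min == max for MFV)."""


class FitError(SaltScreenError):
    """A regression could not be fitted (rank deficiency, too few points)."""


class NoCrossingError(FitError):
    """A flat dose-response line never reaches the target injury level."""
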