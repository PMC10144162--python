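"""Exception hierarchy shared across the package."""


class FloralintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FloralintError):
    """A file does not conform to the expected format (missing column, bad Newick)."""


class ValidationError(FloralintError):
    """Parsed content violates a documented invariant."""


class DegenerateTraitError(ValidationError):
    """A trait column is constant, so its correlations are undefined."""


class NumericError(FloralintError):
    """A numeric operation failed (non-positive-definite covariance, rank deficiency)."""
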