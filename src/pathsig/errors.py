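"""Exception hierarchy.

``FormatError`` covers malformed input files (missing columns, dimension
mismatches); ``ValidationError`` covers well-formed inputs that violate a
domain invariant (negative expression, pseudotime outside [0, 1], duplicate
cell ids).  Both derive from ``ValueError`` so callers that do not care about
the distinction can catch a single builtin type.
"""


class PathsigError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(PathsigError):
    """An input file is structurally malformed."""


class ValidationError(PathsigError):
    """An input violates a domain invariant."""
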