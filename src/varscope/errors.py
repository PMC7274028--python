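"""Exception hierarchy.

Every error raised by the library derives from :class:`VarscopeError` so the
CLI can map failures to a single-line message and a nonzero exit code.
"""


class VarscopeError(Exception):
    """Base class for all varscope errors."""


class ContigError(VarscopeError):
    """Requested contig is not present in the reference."""


class RangeError(VarscopeError):
    """Requested coordinates fall outside the contig."""


class ParseError(VarscopeError):
    """Malformed input file or record."""


class ValidationError(VarscopeError):
    """Input violates a structural constraint (duplicates, unknown refs)."""


class ReservedNameError(ValidationError):
    """A user name collides with a reserved identifier (#ALL, #RAW)."""


class UnknownSampleError(VarscopeError):
    """A sample id is absent from the VCF header."""


class UnknownNameError(VarscopeError):
    """A sample-expression token matches no accession or group."""


class NameCollisionError(VarscopeError):
    """An inline group redefines an existing group id."""


class ParameterError(VarscopeError):
    """An operation was called with out-of-contract parameters."""


class UnresolvableQueryError(VarscopeError):
    """Region text is neither coordinates nor a known gene id."""


class MalformedRegionError(VarscopeError):
    """Region coordinates are syntactically valid but inconsistent."""


class EmptyRegionError(VarscopeError):
    """No sites remain in the queried region after filtering."""


class EmptySiteError(VarscopeError):
    """A single-site query matched no variant."""
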