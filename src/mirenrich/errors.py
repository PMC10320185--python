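"""Exception hierarchy shared across the package."""


class MirEnrichError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirEnrichError, ValueError):
    """A file does not conform to the expected dialect (missing column, bad line)."""


class EmptyInputError(MirEnrichError, ValueError):
    """An input carries no usable records."""


class DomainError(MirEnrichError, ValueError):
    """Arguments violate a mathematical precondition (invalid urn, empty sample, ...)."""
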