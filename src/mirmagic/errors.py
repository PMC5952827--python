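"""Exception types shared across the package."""


class MirMagicError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirMagicError):
    """A file or record does not conform to the expected text format."""


class DuplicateIdentifierError(MirMagicError):
    """Two reference records share the same miRNA identifier."""


class EmptyReferenceError(MirMagicError):
    """A reference FASTA or miRNA list contains no usable records."""


class GroupConflictError(MirMagicError):
    """A miRNA is assigned to two different functional groups."""


class DomainMismatchError(MirMagicError):
    """Two group tables do not cover the same set of miRNAs."""


class EmptyIndexError(MirMagicError):
    """No miRNA yielded a valid core; the match index would be empty."""


class GenerationError(MirMagicError):
    """The simulator could not satisfy its constraints after bounded retries."""
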