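"""Exception types shared across the package."""


class AssemblageError(Exception):
    """Base class for package errors."""


class FormatError(AssemblageError):
    """A file or table violates its format contract."""


class ConsistencyError(AssemblageError):
    """Inputs that must share identifiers or shapes do not."""


class DegenerateInputError(AssemblageError):
    """Input is structurally valid but analytically degenerate."""
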