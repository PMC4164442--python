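"""Exception types shared across the package."""


class RfmqaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RfmqaError, ValueError):
    """A file could not be parsed in the expected format."""


class AlignmentError(RfmqaError, ValueError):
    """Per-residue tracks do not align with the model sequence."""


class ParameterError(RfmqaError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""
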