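"""Exception hierarchy.

Exit-code mapping used by the CLI: InputError (and subclasses) -> 1,
ModelError (and subclasses) -> 2.
"""


class PairsigError(Exception):
    """Base class for all package errors."""


class InputError(PairsigError):
    """Invalid, empty or inconsistent input data."""


class FormatError(InputError):
    """A file could not be parsed in the expected format."""


class ValidationError(InputError):
    """A record violates a domain invariant (e.g. non-positive survival time)."""


class ModelError(PairsigError):
    """A statistical model could not be fitted or is degenerate."""


class EmptySignatureError(ModelError):
    """The L1 penalty shrank every coefficient to zero at the selected lambda."""
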