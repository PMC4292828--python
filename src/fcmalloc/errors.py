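"""Exception hierarchy.

Validation errors signal a violated precondition on otherwise well-formed
inputs; parse errors signal malformed files. The CLI maps them to exit
codes 2 and 3 respectively.
"""


class FcmAllocError(Exception):
    """Base class for all package errors."""


class ValidationError(FcmAllocError):
    """A precondition or invariant on the inputs was violated."""


class ParseError(FcmAllocError):
    """An input file could not be parsed against its schema."""
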