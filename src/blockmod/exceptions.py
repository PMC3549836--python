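"""Exception hierarchy for blockmod."""


class BlockmodError(Exception):
    """Base class for all blockmod errors."""


class ParseError(BlockmodError):
    """A network or assignment file could not be parsed."""


class ValidationError(BlockmodError):
    """An input violates a documented precondition or invariant."""


class SizeError(BlockmodError):
    """An exact computation was requested on an instance that is too large."""
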