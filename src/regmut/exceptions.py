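"""Exception hierarchy shared by all regmut modules."""


class RegmutError(Exception):
    """Base class for all errors raised by regmut."""


class ParseError(RegmutError):
    """A malformed input file or expression; the message names the location."""


class PredicateSyntaxError(ParseError):
    """Syntax error in a donor-filter predicate; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DataError(RegmutError):
    """Semantically invalid data (wrong shapes, impossible values, missing pieces)."""


class RefMismatchError(DataError):
    """A mutation's declared reference base disagrees with the genome."""


class UndefinedTestError(DataError):
    """A statistical test was requested on data for which it is undefined."""


class DegenerateSignatureError(DataError):
    """Region adjustment removed all probability mass from a signature."""

    def __init__(self, signature_id: str):
        super().__init__(
            f"signature {signature_id!r} has zero mass after region adjustment"
        )
        self.signature_id = signature_id
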