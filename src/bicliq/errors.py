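"""Exception hierarchy shared by all bicliq modules."""


class BicliqError(Exception):
    """Base class for all errors raised by bicliq."""


class FormatError(BicliqError):
    """A file does not conform to the expected dialect.

    Carries the offending path and, when known, the 1-based line number,
    so command-line diagnostics can point at the exact spot.
    """

    def __init__(self, message: str, *, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ValidationError(BicliqError):
    """Content is well-formed but internally inconsistent.

    Typical case: an edge-list header declaring counts that do not match
    the labels and edges actually present in the file.
    """


class CapacityError(BicliqError):
    """A guarded operation was asked to exceed its size limit.

    Raised by the brute-force enumerator when the smaller partite set is
    too large for subset enumeration; use the branch-and-bound algorithm
    instead.
    """
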