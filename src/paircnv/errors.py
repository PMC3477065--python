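"""Exception hierarchy shared by all pipeline stages."""


class PairCnvError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PairCnvError):
    """An in-memory object or parameter set violates a documented invariant."""


class ParseError(ValidationError):
    """A file violates its format contract; carries the path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class PairingError(ValidationError):
    """A patient lacks exactly one primary and one metastasis sample."""


class CnvConflictError(PairCnvError):
    """Overlapping segments of opposite state fully cover the same probe."""


class DegenerateInputError(PairCnvError):
    """Too little data for the requested statistic (e.g. fewer than 2 pairs)."""
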