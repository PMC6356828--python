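"""Exception types shared across the pipeline."""


class HepatargetError(Exception):
    """Base class for all package errors."""


class ParseError(HepatargetError):
    """A file could not be parsed in the declared dialect.

    Carries the path and the 1-based line number of the offending record.
    """

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(HepatargetError):
    """An input violated a documented invariant (bad strand, inverted interval, ...)."""
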