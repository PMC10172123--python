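"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line front end:
0 ok, 2 usage, 3 malformed/inconsistent input, 4 degenerate model fit.
"""


class AsmflagError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(AsmflagError):
    """Malformed or inconsistent input (bad line, unknown contig, off-contig
    coordinates).  Carries enough context to name the offending file/line."""

    exit_code = 3

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateFitError(AsmflagError):
    """A coverage histogram too thin or too uniform to support a mixture fit.

    Callers fitting per-window models should catch this and fall back to the
    whole-genome model."""

    exit_code = 4
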