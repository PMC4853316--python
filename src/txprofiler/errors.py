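"""Exception hierarchy shared by all modules.

``FormatError`` marks malformed input data (CLI exit code 2);
``ValidationError`` marks bad arguments or inconsistent inputs (exit code 1).
"""


class TxProfilerError(Exception):
    """Base class for all txprofiler errors."""


class FormatError(TxProfilerError):
    """Input file violates its declared format (wrong columns, bad value)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)


class ValidationError(TxProfilerError):
    """Arguments or inputs are internally inconsistent."""
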