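"""Exception taxonomy shared across the package."""


class CoralloxError(Exception):
    """Base class for all package errors."""


class FormatError(CoralloxError):
    """Malformed input file (carries file/line diagnostics where known)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class BoundsError(CoralloxError):
    """A coordinate or span falls outside the sequence it addresses."""


class TrimError(CoralloxError):
    """No anchor motif found; carries the best near-miss for diagnostics."""

    def __init__(self, message: str, best_near_miss=None):
        super().__init__(message)
        self.best_near_miss = best_near_miss


class ConfigurationError(CoralloxError):
    """A required reference, table or threshold is missing or inconsistent."""


class ContractError(CoralloxError):
    """An input violates a documented precondition (not a file-format issue)."""
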