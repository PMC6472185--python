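"""Exception hierarchy shared across the package."""


class NCToolsError(Exception):
    """Base class for all package errors."""


class RCCFormatError(NCToolsError):
    """Structural problem in an RCC stream (missing/malformed section)."""


class RCCParseError(NCToolsError):
    """Unparseable content at a specific line of an RCC stream."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DuplicateCodeError(NCToolsError):
    """Duplicate (code_class, gene_name) pair within one sample."""


class ValidationError(NCToolsError):
    """A domain object violates its invariants."""


class PanelMismatchError(NCToolsError):
    """Samples in one experiment do not share an identical probe panel."""

    def __init__(self, message: str, difference: set | None = None):
        super().__init__(message)
        self.difference = difference or set()


class InsufficientControlsError(NCToolsError):
    """Too few control probes to run a QC or normalization step."""


class DomainError(NCToolsError):
    """Numeric input outside the operation's domain (e.g. non-positive counts)."""
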