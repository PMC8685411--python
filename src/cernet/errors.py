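"""Exception hierarchy.

``CernetError`` is the base for everything the library raises on purpose;
the CLI maps it to exit code 3 (data/validation error). Usage errors are
left to the CLI framework (exit code 2).
"""


class CernetError(Exception):
    """Base class for all cernet errors."""


class ValidationError(CernetError):
    """Malformed or inconsistent input data."""


class DesignError(ValidationError):
    """Invalid experimental design (missing group, broken pairing, n too small)."""


class ParseError(ValidationError):
    """Malformed file; message names the offending line."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class DegenerateTestError(CernetError):
    """A test statistic is undefined (zero variance of the differences)."""


class UndefinedCorrelationError(CernetError):
    """Pearson correlation undefined because an input vector is constant."""


class UndefinedRatioError(CernetError):
    """Fold change undefined because a group mean plus pseudocount is zero."""


class MissingReferenceError(ValidationError):
    """qPCR reference gene absent for one or more samples."""
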