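"""Exception hierarchy shared across the package."""


class TangoplanError(Exception):
    """Base class for all package errors."""


class ParseError(TangoplanError):
    """A SMILES string could not be parsed into a molecule."""


class DegenerateMoleculeError(TangoplanError):
    """An operation requires a molecule with at least one heavy atom."""


class TemplateParseError(TangoplanError):
    """A reaction-template line could not be parsed.

    Carries the offending line and its 1-based line number.
    """

    def __init__(self, message: str, line: str = "", lineno: int = 0):
        super().__init__(message)
        self.line = line
        self.lineno = lineno


class ParameterError(TangoplanError):
    """Inconsistent generator or search parameters."""


class PathError(TangoplanError):
    """A required molecule is not on the requested route path."""


class InsufficientDataError(TangoplanError):
    """Too few records or groups to compute a diagnostic."""
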