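"""Exception hierarchy.

All package errors derive from :class:`CntorError` so callers can catch one
base class; the CLI maps them to exit status 3 (data error).
"""


class CntorError(Exception):
    """Base class for all package errors."""


class FormatError(CntorError):
    """A file does not conform to its declared format."""


class SelectionError(CntorError):
    """A selection expression is invalid or selects nothing where atoms are required."""


class ParameterError(CntorError):
    """Missing or invalid per-atom parameters (radius, charge, LJ)."""


class UnparameterizedAtomError(ParameterError):
    """An atom has no entry in the parameter table, even via wildcard fallback."""


class DegenerateFitError(CntorError):
    """Superposition requested on fewer than three non-collinear atoms."""


class AnalysisError(CntorError):
    """An analysis precondition is violated (empty window, bad cutoff, ...)."""
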