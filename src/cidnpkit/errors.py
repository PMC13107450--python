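"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`CidnpKitError`, so callers can catch the package's failures with a
single except clause while still distinguishing the common cases.
"""


class CidnpKitError(Exception):
    """Base class for all cidnpkit errors."""


class ValidationError(CidnpKitError, ValueError):
    """Invalid input data or parameters (wrong shape, sign, ordering...)."""


class DomainError(CidnpKitError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class UnitError(CidnpKitError, ValueError):
    """Unknown or inconsistent physical unit tag."""


class IntegrationError(CidnpKitError, RuntimeError):
    """The ODE integrator failed to produce a solution."""


class UnderDeterminedError(CidnpKitError, ValueError):
    """Fewer data points than free parameters."""


class DegenerateDataError(CidnpKitError, ValueError):
    """Data carry no usable signal (e.g. an all-zero trace)."""


class FitDomainError(CidnpKitError, RuntimeError):
    """A fit converged to a physically inadmissible optimum."""


class NotApplicableError(CidnpKitError, ValueError):
    """A rule was applied outside its regime of validity."""


class NormalizationError(CidnpKitError, ValueError):
    """Profile normalization is degenerate (reference intensity ~ 0)."""


class DegenerateGeometryError(CidnpKitError, ValueError):
    """Collinear or otherwise degenerate coordinates."""


class InsufficientEvidenceError(CidnpKitError, ValueError):
    """Not enough independent observations to attempt a classification."""


class ParseError(CidnpKitError, ValueError):
    """Malformed input file; carries file name and (1-based) line number."""

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
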