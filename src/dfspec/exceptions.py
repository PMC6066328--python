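"""Exception hierarchy.

``DomainError``/``RangeError`` signal bad arguments to pure functions;
``FormatError``/``ValidationError`` signal bad input files; the remaining
errors mark failures of individual analysis stages. The CLI maps these to
distinct exit codes.
"""


class DFSpecError(Exception):
    """Base class for all package errors."""


class DomainError(DFSpecError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class RangeError(DFSpecError, ValueError):
    """A value exceeds a configured physical bound (e.g. extension past F_max)."""


class FormatError(DFSpecError, ValueError):
    """An input file does not follow the documented dialect."""


class ValidationError(DFSpecError, ValueError):
    """A file parsed but its contents violate an invariant."""


class SimulationError(DFSpecError, RuntimeError):
    """The force-curve simulator failed (e.g. root-find non-convergence)."""


class FitError(DFSpecError, RuntimeError):
    """A curve or model fit failed or did not converge."""


class EstimationError(DFSpecError, RuntimeError):
    """A per-event estimate (loading rate) could not be formed."""


class EmptyReportError(DFSpecError, RuntimeError):
    """The pipeline ended with zero accepted events."""
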