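"""Exception hierarchy for focuswalk."""


class FocuswalkError(Exception):
    """Base class for all focuswalk errors."""


class PDBParseError(FocuswalkError):
    """A structure file could not be parsed."""


class EmptyStructureError(FocuswalkError):
    """A structure contained no atoms where at least one was required."""


class ParameterizationError(FocuswalkError):
    """Force-field parameters could not be assigned to one or more atoms."""


class GridSizeError(FocuswalkError):
    """The requested grid exceeds the configured dimension cap."""


class OutOfGridError(FocuswalkError):
    """A point or atom fell outside the grid (or its interior region)."""


class ConvergenceError(FocuswalkError):
    """The iterative solver failed to reach tolerance.

    Carries the residual history in ``residual_history``.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class FocusingError(FocuswalkError):
    """Invalid parent/child geometry or resolution in a focusing run."""


class LatticeError(FocuswalkError):
    """Invalid pose-lattice specification or index."""


class ConfigError(FocuswalkError):
    """Invalid run configuration; message aggregates all violations."""
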