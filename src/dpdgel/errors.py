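"""Exception hierarchy for dpdgel."""


class DpdGelError(Exception):
    """Base class for all dpdgel errors."""


class ConfigurationError(DpdGelError):
    """Invalid or inconsistent run configuration (e.g. unseeded RNG)."""


class StateError(DpdGelError):
    """Simulation state is invalid (non-finite coordinates, bad bonds)."""


class InstabilityError(DpdGelError):
    """Integration became unstable; carries the step index where it failed."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateBondError(DpdGelError):
    """A bond of zero length with nonzero stiffness has no defined direction."""


class CompositionError(DpdGelError):
    """Bead composition cannot be realised (e.g. rounding leaves no crosslinker)."""


class TopologyError(DpdGelError):
    """Network graph construction failed (e.g. a bond references a water bead)."""


class SolverError(DpdGelError):
    """A root-finding or fitting step failed; message carries diagnostics."""


class ParseError(DpdGelError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FiniteExtensibilityError(DpdGelError):
    """Chain stretch reached the inverse-Langevin singularity (lambda_c * l0 >= 1)."""
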