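"""Exception hierarchy shared across the package."""


class SynoptError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SynoptError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(SynoptError):
    """Musculotendon length at or below tendon slack length.

    A rigid tendon cannot be shorter than its slack length; the fiber state
    is undefined there.
    """

    def __init__(self, muscle: str, frame: int, lmt: float, lts: float):
        self.muscle = muscle
        self.frame = frame
        super().__init__(
            f"musculotendon length {lmt:.6g} m <= tendon slack length "
            f"{lts:.6g} m for muscle {muscle!r} at frame {frame}"
        )


class InfeasibleFrameError(SynoptError):
    """No activation vector in [0, 1]^m satisfies the moment constraints."""

    def __init__(self, frame: int, best_residual: float, tol: float):
        self.frame = frame
        self.best_residual = best_residual
        self.tol = tol
        super().__init__(
            f"frame {frame}: moment equality constraints unsatisfiable within "
            f"bounds (best scaled residual {best_residual:.3g} > tol {tol:.3g})"
        )


class OptimizationFailureError(SynoptError):
    """All multistarts of a nonlinear solve failed to converge."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class TrialFormatError(SynoptError):
    """A trial bundle on disk is missing datasets or internally inconsistent."""


class UndefinedMetricError(SynoptError):
    """A metric is undefined for this input (e.g. all-zero reference)."""
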