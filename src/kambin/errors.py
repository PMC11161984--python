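"""Exception hierarchy for the kambin package."""

from __future__ import annotations


class KambinError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(KambinError):
    """A geometric precondition is violated (degenerate or non-right input)."""


class ProjectionDegenerateError(InvalidGeometryError):
    """A direction projects to (numerically) zero in the requested plane."""


class NoIntersectionError(KambinError):
    """A ray does not intersect the requested plane."""


class IntersectionBehindRayError(NoIntersectionError):
    """The line through the ray meets the plane, but behind the ray origin."""

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


class NoSolutionError(KambinError):
    """The inverse constructor failed to reach the requested targets.

    Carries the best residual achieved so callers can diagnose infeasibility.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class ValidationError(KambinError):
    """A case record or configuration failed schema validation."""


class DegenerateTestError(KambinError):
    """A statistical test cannot be computed on the given data."""


class ConfigurationError(KambinError):
    """A generator or pipeline configuration is unusable."""


class MeasurementError(KambinError):
    """A per-case measurement failed; wraps the stage error with the case id."""

    def __init__(self, case_id: str, stage: str, cause: Exception):
        super().__init__(f"case {case_id!r}: {stage}: {cause}")
        self.case_id = case_id
        self.stage = stage
        self.cause = cause
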