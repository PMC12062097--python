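"""Shared exception types."""

__all__ = [
    "RegimeError",
    "ResonanceError",
    "NoCandidateError",
    "NoMinimiserError",
    "BoundaryLeakError",
    "InstabilityError",
]


class RegimeError(ValueError):
    """Parameter regime does not support the requested construction (e.g. gamma <= 1)."""


class ResonanceError(ValueError):
    """Environment mode frequency coincides with the intrinsic frequency.

    The particular-solution denominator vanishes and the printed solution
    family degenerates; no secular solution is attempted.
    """


class NoCandidateError(ValueError):
    """The constraint system for a candidate profile is singular at this half-width."""


class NoMinimiserError(RuntimeError):
    """No admissible half-width was found anywhere in the search range."""


class BoundaryLeakError(ValueError):
    """A density carries non-negligible mass at the domain boundary."""


class InstabilityError(RuntimeError):
    """The explicit time stepper produced NaNs or excessive negative mass."""
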