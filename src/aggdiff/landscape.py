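"""Heterogeneous environment profiles on the dimensionless domain [-1, 1].

The environment ``A(x)`` enters the models only through its value and its
gradient.  Three concrete forms are provided:

* :class:`FourierEnvironment` -- a truncated Fourier series, period 2;
* :class:`SingleClumpEnvironment` -- one cosine bump of half-width ``1/n``
  centred on the origin, ``A(x) = a_n [1 + cos(n pi x)]`` for ``|x| < 1/n``;
* :class:`TwoClumpEnvironment` -- the complementary two-bump profile
  ``A(x) = a_4 [1 - cos(4 pi x)]`` for ``|x| < 1/2``.

All forms evaluate to exactly ``0.0`` outside their support so the
environmental advection vanishes identically there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "DomainError",
    "FourierEnvironment",
    "SingleClumpEnvironment",
    "TwoClumpEnvironment",
    "Environment",
    "eval_environment",
    "environment_gradient",
    "make_fourier",
]

#: half-period of the dimensionless domain
DOMAIN_HALF_WIDTH = 1.0

_DOMAIN_TOL = 1e-12


class DomainError(ValueError):
    """Raised when a position lies outside the dimensionless domain [-1, 1]."""


def _check_domain(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > DOMAIN_HALF_WIDTH + _DOMAIN_TOL):
        bad = np.asarray(x)[np.abs(x) > DOMAIN_HALF_WIDTH + _DOMAIN_TOL]
        raise DomainError(
            f"position(s) outside [-1, 1]: {bad.flat[0]:g} (and possibly others)"
        )
    return x


@dataclass(frozen=True)
class FourierEnvironment:
    """Environment given by a truncated Fourier series of period 2.

    ``A(x) = a0 + sum_n [ a_n cos(n pi x) + b_n sin(n pi x) ]``.
    """

    a0: float = 0.0
    cosine_coeffs: Sequence[float] = field(default_factory=tuple)
    sine_coeffs: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cosine_coeffs", tuple(float(c) for c in self.cosine_coeffs))
        object.__setattr__(self, "sine_coeffs", tuple(float(c) for c in self.sine_coeffs))

    def value(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.a0, dtype=float)
        for n, a in enumerate(self.cosine_coeffs, start=1):
            if a != 0.0:
                out += a * np.cos(n * np.pi * x)
        for n, b in enumerate(self.sine_coeffs, start=1):
            if b != 0.0:
                out += b * np.sin(n * np.pi * x)
        return out

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for n, a in enumerate(self.cosine_coeffs, start=1):
            if a != 0.0:
                out -= a * n * np.pi * np.sin(n * np.pi * x)
        for n, b in enumerate(self.sine_coeffs, start=1):
            if b != 0.0:
                out += b * n * np.pi * np.cos(n * np.pi * x)
        return out


@dataclass(frozen=True)
class SingleClumpEnvironment:
    """A single clump of attractive material centred on the origin.

    ``A(x) = amplitude * [1 + cos(n pi x)]`` for ``|x| < 1/n``, zero
    otherwise.  The profile is C^1: value and slope both vanish at the clump
    edge ``|x| = 1/n``.
    """

    n: int
    amplitude: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"mode index n must be a positive integer, got {self.n}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "amplitude", float(self.amplitude))

    @property
    def half_width(self) -> float:
        """Half-width of the clump support, ``1/n``."""
        return 1.0 / self.n

    def value(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < self.half_width
        out = np.zeros_like(x, dtype=float)
        xin = np.where(inside, x, 0.0)
        out = np.where(inside, self.amplitude * (1.0 + np.cos(self.n * np.pi * xin)), 0.0)
        return out

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < self.half_width
        xin = np.where(inside, x, 0.0)
        return np.where(inside, -self.amplitude * self.n * np.pi * np.sin(self.n * np.pi * xin), 0.0)

    def second_derivative(self, x):
        """d^2 A / dx^2 piecewise (discontinuous at the clump edge)."""
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < self.half_width
        xin = np.where(inside, x, 0.0)
        w = self.n * np.pi
        return np.where(inside, -self.amplitude * w * w * np.cos(w * xin), 0.0)


@dataclass(frozen=True)
class TwoClumpEnvironment:
    """Two resource clumps: ``A(x) = a4 [1 - cos(4 pi x)]`` on ``|x| < 1/2``.

    Maxima of height ``2 a4`` sit at ``x = +-1/4``; the origin is a trough.
    """

    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        object.__setattr__(self, "amplitude", float(self.amplitude))

    @property
    def half_width(self) -> float:
        return 0.5

    def value(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < 0.5
        xin = np.where(inside, x, 0.0)
        return np.where(inside, self.amplitude * (1.0 - np.cos(4.0 * np.pi * xin)), 0.0)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < 0.5
        xin = np.where(inside, x, 0.0)
        return np.where(inside, self.amplitude * 4.0 * np.pi * np.sin(4.0 * np.pi * xin), 0.0)


Environment = Union[FourierEnvironment, SingleClumpEnvironment, TwoClumpEnvironment]


def eval_environment(env: Environment, x):
    """Evaluate ``A(x)``; vectorises over a grid of positions.

    Raises :class:`DomainError` for positions outside [-1, 1].
    """
    x = _check_domain(x)
    return env.value(x)


def environment_gradient(env: Environment, x):
    """Evaluate ``dA/dx`` from the closed-form derivative of each piece."""
    x = _check_domain(x)
    return env.gradient(x)


def make_fourier(env: Environment, n_modes: int, quadrature_points: int | None = None) -> FourierEnvironment:
    """Project an environment onto a truncated Fourier series on [-1, 1].

    Trapezoidal quadrature on a periodic grid; the number of quadrature
    points defaults to ``max(8 * n_modes, 1024)`` so the rule is applied at
    well above eight points per highest retained mode.
    """
    if n_modes < 1:
        raise ValueError(f"n_modes must be >= 1, got {n_modes}")
    if quadrature_points is None:
        quadrature_points = max(8 * n_modes, 1024)
    M = int(quadrature_points)
    # periodic trapezoid == uniform Riemann sum on [-1, 1)
    x = -1.0 + 2.0 * np.arange(M) / M
    fx = env.value(x)
    dx = 2.0 / M
    a0 = 0.5 * np.sum(fx) * dx
    ns = np.arange(1, n_modes + 1)[:, None]
    cos_part = np.cos(ns * np.pi * x[None, :])
    sin_part = np.sin(ns * np.pi * x[None, :])
    a = cos_part @ fx * dx
    b = sin_part @ fx * dx
    # snap round-off to exact zero so trivially-sparse projections stay sparse
    a[np.abs(a) < 1e-14] = 0.0
    b[np.abs(b) < 1e-14] = 0.0
    return FourierEnvironment(a0=float(a0), cosine_coeffs=tuple(a), sine_coeffs=tuple(b))
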