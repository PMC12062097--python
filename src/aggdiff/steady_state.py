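"""Closed-form steady-state families and the constrained single-aggregation candidate.

Two model families are supported, both with quadratic diffusion:

* ``fourth_order`` -- the local Cahn-Hilliard-type approximation, whose
  steady states on a support component satisfy
  ``c + A = (1 - gamma) u - (gamma sigma^2 / 2) u''``;
* ``laplace`` -- the nonlocal model with Laplace kernel, whose steady
  states satisfy ``m^2 c + m^2 A - A'' = m^2 (1 - gamma) u - u''``.

For ``gamma > 1`` the homogeneous part of the solution is oscillatory with
intrinsic frequency ``omega`` (``sqrt(2 (gamma - 1) / (gamma sigma^2))`` or
``m sqrt(gamma - 1)``), and the single-aggregation candidate supported on
``[-r, r]`` is a sum of a constant, the environment-mode cosine response,
and a homogeneous cosine -- with the constant and the homogeneous amplitude
pinned down by the mass constraint and continuity at the support edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

import numpy as np
from scipy.optimize import brentq

from .errors import NoCandidateError, RegimeError, ResonanceError
from .landscape import SingleClumpEnvironment

__all__ = [
    "ModelParams",
    "CandidateSolution",
    "HomogeneousMinimiser",
    "AdmissibilityResult",
    "r0_of",
    "homogeneous_minimiser",
    "mode_factor",
    "build_candidate",
    "candidate_value",
    "is_admissible",
    "steady_residual",
]

RESONANCE_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless model parameters.

    Exactly one of ``sigma`` (fourth-order family) or ``m`` (Laplace
    family) is required by the active family.
    """

    gamma: float
    p: float = 1.0
    model_family: Literal["fourth_order", "laplace"] = "fourth_order"
    sigma: float | None = None
    m: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.p <= 0:
            raise ValueError(f"total mass p must be > 0, got {self.p}")
        if self.model_family == "fourth_order":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("fourth_order family requires sigma > 0")
        elif self.model_family == "laplace":
            if self.m is None or self.m <= 0:
                raise ValueError("laplace family requires m > 0")
        else:
            raise ValueError(f"unknown model family {self.model_family!r}")

    @property
    def omega(self) -> float:
        """Intrinsic frequency of the oscillatory homogeneous solution (gamma > 1)."""
        if self.gamma <= 1:
            raise RegimeError(
                f"oscillatory homogeneous family requires gamma > 1, got gamma={self.gamma}"
            )
        if self.model_family == "fourth_order":
            return math.sqrt(2.0 * (self.gamma - 1.0) / (self.gamma * self.sigma**2))
        return self.m * math.sqrt(self.gamma - 1.0)

    @property
    def r0(self) -> float:
        """Half-width of one homogeneous oscillation lobe, ``pi / omega``."""
        return math.pi / self.omega

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def r0_of(gamma: float, sigma: float) -> float:
    """Half-width of the homogeneous-landscape minimiser (fourth-order family).

    ``r0 = pi * sqrt(gamma sigma^2 / (2 (gamma - 1)))``; requires gamma > 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if gamma <= 1:
        raise RegimeError(f"r0 requires gamma > 1, got gamma={gamma}")
    return math.pi * math.sqrt(gamma * sigma**2 / (2.0 * (gamma - 1.0)))


@dataclass(frozen=True)
class HomogeneousMinimiser:
    """Minimum-energy profile on a flat landscape: a single cosine lobe.

    ``u(x) = (p / 2 r0) [1 + cos(pi x / r0)]`` on ``|x| < r0``, zero outside.
    """

    r0: float
    p: float

    def value(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < self.r0
        xin = np.where(inside, x, 0.0)
        amp = self.p / (2.0 * self.r0)
        return np.where(inside, amp * (1.0 + np.cos(np.pi * xin / self.r0)), 0.0)

    @property
    def peak(self) -> float:
        return self.p / self.r0


def homogeneous_minimiser(params: ModelParams) -> HomogeneousMinimiser:
    """The flat-landscape minimum-energy profile for the fourth-order family."""
    if params.model_family != "fourth_order":
        raise RegimeError("homogeneous minimiser closed form is for the fourth_order family")
    return HomogeneousMinimiser(r0=r0_of(params.gamma, params.sigma), p=params.p)


def mode_factor(params: ModelParams, n: int) -> float:
    """Multiplier mapping the environment's mode-n coefficient into the particular solution.

    Fourth-order family: ``2 / (2 (1 - gamma) + gamma sigma^2 n^2 pi^2)``.
    Laplace family: ``(n^2 pi^2 + m^2) / (n^2 pi^2 + m^2 (1 - gamma))``.

    Raises :class:`ResonanceError` when the denominator vanishes (the clump
    frequency matches the intrinsic frequency and the family degenerates).
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"mode index must be a positive integer, got {n}")
    w2 = (n * math.pi) ** 2
    if params.model_family == "fourth_order":
        denom = 2.0 * (1.0 - params.gamma) + params.gamma * params.sigma**2 * w2
        numer = 2.0
    else:
        denom = w2 + params.m**2 * (1.0 - params.gamma)
        numer = w2 + params.m**2
    if abs(denom) < RESONANCE_TOL:
        raise ResonanceError(
            f"mode n={n} resonates with the intrinsic frequency (denominator {denom:.3e})"
        )
    return numer / denom


@dataclass(frozen=True)
class CandidateSolution:
    """Symmetric single-aggregation steady-state candidate on ``[-r, r]``.

    On the clump overlap ``|x| <= min(r, 1/n)`` the profile reads
    ``alpha0 + alpha_n [1 + cos(n pi x)] + Q cos(omega x)``; on the
    remainder of the support (present only when ``r > 1/n``) the
    clump-mode term is absent.  ``P`` (the odd homogeneous amplitude) is
    fixed at zero by the symmetry restriction.
    """

    r: float
    alpha0: float
    alpha_n: float
    Q: float
    env: SingleClumpEnvironment
    params: ModelParams
    P: float = 0.0

    @property
    def omega(self) -> float:
        return self.params.omega

    @property
    def clump_edge(self) -> float:
        return self.env.half_width

    def _pieces(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        in_support = ax <= self.r + 1e-15
        in_clump = in_support & (ax < self.clump_edge)
        return x, in_support, in_clump

    def value(self, x):
        x, in_support, in_clump = self._pieces(x)
        n = self.env.n
        base = self.alpha0 + self.Q * np.cos(self.omega * x)
        out = np.where(in_support, base, 0.0)
        out = np.where(in_clump, out + self.alpha_n * (1.0 + np.cos(n * np.pi * x)), out)
        return out

    def derivative(self, x):
        x, in_support, in_clump = self._pieces(x)
        n = self.env.n
        base = -self.Q * self.omega * np.sin(self.omega * x)
        out = np.where(in_support, base, 0.0)
        out = np.where(in_clump, out - self.alpha_n * n * np.pi * np.sin(n * np.pi * x), out)
        return out

    def second_derivative(self, x):
        """Exact piecewise second derivative (used by residual and energy checks)."""
        x, in_support, in_clump = self._pieces(x)
        n = self.env.n
        base = -self.Q * self.omega**2 * np.cos(self.omega * x)
        out = np.where(in_support, base, 0.0)
        out = np.where(in_clump, out - self.alpha_n * (n * np.pi) ** 2 * np.cos(n * np.pi * x), out)
        return out

    def mass(self) -> float:
        """Closed-form integral of the profile over its support."""
        r, w = self.r, self.omega
        n = self.env.n
        total = 2.0 * r * self.alpha0 + (2.0 / w) * self.Q * math.sin(w * r)
        if r < self.clump_edge:
            total += self.alpha_n * (2.0 * r + (2.0 / (n * math.pi)) * math.sin(n * math.pi * r))
        else:
            total += 2.0 * self.alpha_n / n
        return total

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "alpha0": self.alpha0,
            "alpha_n": self.alpha_n,
            "Q": self.Q,
            "P": self.P,
            "n": self.env.n,
            "amplitude": self.env.amplitude,
            "gamma": self.params.gamma,
            "sigma": self.params.sigma,
            "m": self.params.m,
            "p": self.params.p,
            "model_family": self.params.model_family,
        }


def build_candidate(
    params: ModelParams, env: SingleClumpEnvironment, r: float
) -> CandidateSolution:
    """Construct the unique symmetric candidate of half-width ``r``.

    The clump-mode amplitude is ``alpha_n = mode_factor * a_n``; the
    remaining pair ``(alpha0, Q)`` solves the mass constraint and the
    continuity condition ``u(+-r) = 0`` simultaneously as a 2x2 linear
    system (the two printed constraints reference each other's unknown,
    so substitution order does not apply).
    """
    if not (0.0 < r <= 1.0):
        raise ValueError(f"half-width r must lie in (0, 1], got {r}")
    if params.gamma <= 1.0:
        raise RegimeError(f"candidate construction requires gamma > 1, got {params.gamma}")
    w = params.omega
    n = env.n
    alpha_n = mode_factor(params, n) * env.amplitude

    # rows: [mass ; continuity at r] against unknowns (alpha0, Q)
    a11 = 2.0 * r
    a12 = (2.0 / w) * math.sin(w * r)
    a21 = 1.0
    a22 = math.cos(w * r)
    if r < env.half_width:
        b1 = params.p - alpha_n * (2.0 * r + (2.0 / (n * math.pi)) * math.sin(n * math.pi * r))
        b2 = -alpha_n * (1.0 + math.cos(n * math.pi * r))
    else:
        b1 = params.p - 2.0 * alpha_n / n
        b2 = 0.0
    det = a11 * a22 - a12 * a21
    scale = max(abs(a11), abs(a12), abs(a21), abs(a22))
    if abs(det) < 1e-12 * scale * scale:
        raise NoCandidateError(
            f"constraint system singular at r={r:.6g} (det={det:.3e}); no candidate here"
        )
    alpha0 = (b1 * a22 - b2 * a12) / det
    Q = (a11 * b2 - a21 * b1) / det
    return CandidateSolution(r=r, alpha0=alpha0, alpha_n=alpha_n, Q=Q, env=env, params=params)


def candidate_value(sol: CandidateSolution, x):
    """Evaluate the candidate profile (zero outside ``[-r, r]``)."""
    return sol.value(x)


class AdmissibilityResult(NamedTuple):
    admissible: bool
    min_value: float


#: round-off floor distinguishing genuine negativity from noise
ADMISSIBILITY_TOL = -1e-12


def is_admissible(sol: CandidateSolution, n_grid: int = 4096) -> AdmissibilityResult:
    """Whether the candidate is non-negative on its support.

    The minimum is taken over a dense grid plus interior critical points
    located by bracketed root-finding on the (piecewise trigonometric)
    derivative, so narrow dips are not missed.
    """
    r = sol.r
    xs = np.linspace(-r, r, n_grid)
    vals = sol.value(xs)
    min_val = float(vals.min())
    # refine interior critical points: sign changes of the derivative
    dv = sol.derivative(xs)
    sign_change = np.nonzero(np.sign(dv[:-1]) * np.sign(dv[1:]) < 0)[0]
    for i in sign_change:
        try:
            xc = brentq(lambda x: float(sol.derivative(x)), xs[i], xs[i + 1], xtol=1e-14)
        except ValueError:  # pragma: no cover - bracket degenerated
            continue
        min_val = min(min_val, float(sol.value(xc)))
    return AdmissibilityResult(min_val >= ADMISSIBILITY_TOL, min_val)


def steady_residual(sol: CandidateSolution, n_grid: int = 4096) -> float:
    """Max absolute residual of the defining steady-state ODE on the support interior.

    The free constant ``c`` is fitted by least squares (its optimum is the
    mean of the constraint expression over the sample grid).  Derivatives
    of the candidate are exact piecewise cosines; no differencing error
    enters.
    """
    params = sol.params
    r = sol.r
    # offset grid avoids evaluating exactly on the piecewise breakpoints
    xs = np.linspace(-r, r, n_grid + 1)[:-1] + r / n_grid
    u = sol.value(xs)
    upp = sol.second_derivative(xs)
    A = sol.env.value(xs)
    if params.model_family == "fourth_order":
        # c + A = (1 - gamma) u - (gamma sigma^2 / 2) u''
        lhs = (1.0 - params.gamma) * u - 0.5 * params.gamma * params.sigma**2 * upp - A
        c = float(lhs.mean())
        return float(np.abs(lhs - c).max())
    # m^2 c + m^2 A - A'' = m^2 (1 - gamma) u - u''
    m2 = params.m**2
    App = sol.env.second_derivative(xs)
    lhs = m2 * (1.0 - params.gamma) * u - upp - m2 * A + App
    c = float(lhs.mean())
    return float(np.abs(lhs - c).max() / m2)
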