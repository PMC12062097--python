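"""Energy functionals and rapid minimisation over the aggregation half-width.

Two functionals are used, one per model family:

* ``E1[u] = int u [ (1 - gamma) u - 2 A - gamma K_m * u ] dx`` (nonlocal);
* ``E2[u] = int u [ (1 - gamma) u - 2 A - (gamma sigma^2 / 2) u'' ] dx`` (local).

Both are non-increasing along trajectories of the corresponding PDE while
``u`` stays non-negative, so their minimisers over the admissible candidate
family predict the emergent steady state.  For the single-clump candidate
``E2`` collapses to a closed form because the homogeneous-cosine bracket
cancels identically (``(gamma sigma^2 / 2) omega^2 = gamma - 1``), leaving
only elementary trigonometric integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import simpson

from .errors import (
    BoundaryLeakError,
    NoCandidateError,
    NoMinimiserError,
    RegimeError,
    ResonanceError,
)
from .kernels import Kernel, LaplaceKernel, convolve
from .landscape import Environment, SingleClumpEnvironment
from .steady_state import (
    CandidateSolution,
    ModelParams,
    build_candidate,
    is_admissible,
)

__all__ = [
    "EnergyCurve",
    "MinimisationResult",
    "energy_E2_quadrature",
    "energy_E1_quadrature",
    "energy_E2_closed",
    "energy_E1_candidate",
    "minimise_energy",
    "energy_curve",
    "laplace_convolve_candidate",
]


# --------------------------------------------------------------------------
# quadrature routes

def _check_boundary_leak(u: np.ndarray, dx: float, p_scale: float) -> None:
    edge_mass = (abs(float(u[0])) + abs(float(u[-1]))) * dx
    if edge_mass > 1e-9 * max(p_scale, 1.0):
        raise BoundaryLeakError(
            f"density carries mass {edge_mass:.3e} at the grid edge; "
            "the energy integral would be truncated"
        )


def _candidate_support_grid(sol: CandidateSolution, n_per_piece: int = 2049):
    """Simpson nodes over the support, split at the clump edge when it is interior.

    Piece endpoints are nudged inward by 1e-10 so each piece samples its own
    branch of the (discontinuous) second derivative; the omitted slivers
    contribute far below the 1e-6 comparison tolerance.
    """
    r, edge = sol.r, sol.clump_edge
    breaks = [-r, r]
    if edge < r:
        breaks = [-r, -edge, edge, r]
    nudge = 1e-10
    pieces = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        pieces.append(np.linspace(lo + nudge, hi - nudge, n_per_piece))
    return pieces


def energy_E2_quadrature(u, env: Environment, gamma: float, sigma: float,
                         x: np.ndarray | None = None, dx: float | None = None) -> float:
    """E2 by composite quadrature.

    ``u`` may be a :class:`CandidateSolution` (exact piecewise second
    derivatives, Simpson on the support) or a gridded density (centred
    second differences on a uniform grid given by ``x`` or ``dx``).
    """
    if isinstance(u, CandidateSolution):
        total = 0.0
        for xs in _candidate_support_grid(u):
            vals = u.value(xs)
            upp = u.second_derivative(xs)
            A = env.value(xs)
            integrand = vals * ((1.0 - gamma) * vals - 2.0 * A - 0.5 * gamma * sigma**2 * upp)
            total += float(simpson(integrand, x=xs))
        return total

    u = np.asarray(u, dtype=float)
    if dx is None:
        if x is None:
            raise ValueError("gridded energy evaluation needs x or dx")
        dx = float(x[1] - x[0])
    if x is None:
        raise ValueError("gridded energy evaluation needs the grid positions x")
    _check_boundary_leak(u, dx, float(np.sum(u) * dx))
    upp = np.empty_like(u)
    upp[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / dx**2
    upp[0] = (u[1] - u[0]) / dx**2
    upp[-1] = (u[-2] - u[-1]) / dx**2
    A = env.value(np.asarray(x, dtype=float))
    integrand = u * ((1.0 - gamma) * u - 2.0 * A - 0.5 * gamma * sigma**2 * upp)
    return float(np.sum(integrand) * dx)


def energy_E1_quadrature(u, env: Environment, gamma: float, kernel: Kernel,
                         x: np.ndarray | None = None, dx: float | None = None) -> float:
    """E1 by quadrature, with ``K * u`` from the kernels-module convolution.

    For a :class:`CandidateSolution` with a Laplace kernel the convolution
    is evaluated semi-analytically (exact integration of exponentials
    against the piecewise cosines).
    """
    if isinstance(u, CandidateSolution):
        if isinstance(kernel, LaplaceKernel):
            total = 0.0
            for xs in _candidate_support_grid(u):
                vals = u.value(xs)
                A = env.value(xs)
                conv = laplace_convolve_candidate(u, xs, kernel.rate)
                integrand = vals * ((1.0 - gamma) * vals - 2.0 * A - gamma * conv)
                total += float(simpson(integrand, x=xs))
            return total
        # numeric fallback: sample on a fine uniform grid
        n = 8193
        xs = np.linspace(-1.0, 1.0, n)
        h = xs[1] - xs[0]
        return energy_E1_quadrature(u.value(xs), env, gamma, kernel, x=xs, dx=h)

    u = np.asarray(u, dtype=float)
    if dx is None:
        if x is None:
            raise ValueError("gridded energy evaluation needs x or dx")
        dx = float(x[1] - x[0])
    if x is None:
        raise ValueError("gridded energy evaluation needs the grid positions x")
    _check_boundary_leak(u, dx, float(np.sum(u) * dx))
    conv = convolve(kernel, u, dx, x=x)
    A = env.value(np.asarray(x, dtype=float))
    integrand = u * ((1.0 - gamma) * u - 2.0 * A - gamma * conv)
    return float(np.sum(integrand) * dx)


# --------------------------------------------------------------------------
# semi-analytic Laplace convolution

def _laplace_segment_cos(x: np.ndarray, y1: float, y2: float, a: float, m: float) -> np.ndarray:
    """``int_{y1}^{y2} (m/2) exp(-m |x - y|) cos(a y) dy`` vectorised over x.

    Uses the elementary antiderivatives of ``exp(+-m y) cos(a y)``; the
    segment is split at ``y = x`` where it straddles the evaluation point.
    """
    x = np.asarray(x, dtype=float)
    denom = m * m + a * a
    s = np.clip(x, y1, y2)  # split point

    def below(y):  # integral of (m/2) e^{m(y-x)} cos(a y), y <= x
        return 0.5 * m * np.exp(m * (y - x)) * (m * np.cos(a * y) + a * np.sin(a * y)) / denom

    def above(y):  # integral of (m/2) e^{m(x-y)} cos(a y), y >= x
        return 0.5 * m * np.exp(m * (x - y)) * (-m * np.cos(a * y) + a * np.sin(a * y)) / denom

    return (below(s) - below(y1)) + (above(y2) - above(s))


def laplace_convolve_candidate(sol: CandidateSolution, x, m: float) -> np.ndarray:
    """Exact ``K_m * u`` for a candidate profile, evaluated at positions ``x``."""
    x = np.asarray(x, dtype=float)
    r, edge = sol.r, sol.clump_edge
    n = sol.env.n
    w = sol.omega
    out = np.zeros_like(x)
    # constant + homogeneous cosine live on the whole support
    out += sol.alpha0 * _laplace_segment_cos(x, -r, r, 0.0, m)
    out += sol.Q * _laplace_segment_cos(x, -r, r, w, m)
    # clump-mode terms live on the overlap with the clump
    b = min(r, edge)
    out += sol.alpha_n * _laplace_segment_cos(x, -b, b, 0.0, m)
    out += sol.alpha_n * _laplace_segment_cos(x, -b, b, n * math.pi, m)
    return out


# --------------------------------------------------------------------------
# closed form

def energy_E2_closed(sol: CandidateSolution, env: SingleClumpEnvironment) -> float:
    """Closed-form E2 of a fourth-order candidate (elementary trig integrals).

    On the clump overlap the effective integrand weight is
    ``(1 - gamma)(alpha0 + alpha_n) - 2 a_n - a_n cos(n pi x)``; outside it
    (when ``r > 1/n``) the weight is ``(1 - gamma) alpha0``.  Equality with
    :func:`energy_E2_quadrature` is exact analytically.
    """
    params = sol.params
    if params.model_family != "fourth_order":
        raise ValueError("closed-form E2 applies to the fourth_order family")
    gamma = params.gamma
    a_n = env.amplitude
    n = env.n
    r, w = sol.r, sol.omega
    alpha0, alpha_n, Q = sol.alpha0, sol.alpha_n, sol.Q
    npi = n * math.pi

    def int_u_cos(lo: float, hi: float) -> float:
        """int of u(x) cos(n pi x) over [-hi..-lo] + [lo..hi] style symmetric range.

        Here called with lo = 0 implied: integrates over [-hi, hi] for the
        clump-overlap region where u carries the clump-mode term.
        """
        # symmetric integral over [-hi, hi] of
        # [(alpha0 + alpha_n) + alpha_n cos(npi x) + Q cos(w x)] cos(npi x)
        t1 = (alpha0 + alpha_n) * (2.0 / npi) * math.sin(npi * hi)
        t2 = alpha_n * (hi + math.sin(2.0 * npi * hi) / (2.0 * npi))
        if abs(w - npi) < 1e-12:  # resonance is guarded upstream; keep safe anyway
            t3 = Q * (hi + math.sin(2.0 * npi * hi) / (2.0 * npi))
        else:
            t3 = Q * (
                math.sin((w - npi) * hi) / (w - npi) + math.sin((w + npi) * hi) / (w + npi)
            )
        return t1 + t2 + t3

    if r < sol.clump_edge:
        # single region: weight [(1-gamma)(alpha0+alpha_n) - 2 a_n] times mass p,
        # minus a_n times int u cos(n pi x)
        mass = sol.mass()
        return ((1.0 - gamma) * (alpha0 + alpha_n) - 2.0 * a_n) * mass - a_n * int_u_cos(0.0, r)

    edge = sol.clump_edge
    # mass inside the clump
    mass_in = (alpha0 + alpha_n) * 2.0 * edge + Q * (2.0 / w) * math.sin(w * edge)
    # one-sided mass outside the clump (clump-mode term absent there)
    mass_out_one = alpha0 * (r - edge) + (Q / w) * (math.sin(w * r) - math.sin(w * edge))
    inner = ((1.0 - gamma) * (alpha0 + alpha_n) - 2.0 * a_n) * mass_in - a_n * int_u_cos(0.0, edge)
    outer = 2.0 * (1.0 - gamma) * alpha0 * mass_out_one
    return inner + outer


def energy_E1_candidate(sol: CandidateSolution, env: SingleClumpEnvironment) -> float:
    """E1 of a Laplace-family candidate via the semi-analytic convolution."""
    params = sol.params
    kernel = LaplaceKernel(rate=params.m)
    return energy_E1_quadrature(sol, env, params.gamma, kernel)


# --------------------------------------------------------------------------
# minimisation over r

@dataclass
class EnergyCurve:
    """Energy as a function of the half-width r, restricted to admissible r."""

    r_values: np.ndarray
    energies: np.ndarray
    argmin_r: float | None = None
    minimum_energy: float | None = None
    empty: bool = field(default=False)

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.empty = self.r_values.size == 0
        if not self.empty:
            i = int(np.argmin(self.energies))
            self.argmin_r = float(self.r_values[i])
            self.minimum_energy = float(self.energies[i])


@dataclass(frozen=True)
class MinimisationResult:
    r: float
    solution: CandidateSolution
    energy: float


def _candidate_energy(params: ModelParams, env: SingleClumpEnvironment, r: float):
    """(candidate, energy) at half-width r, or None when no admissible candidate exists."""
    try:
        sol = build_candidate(params, env, r)
    except ResonanceError:
        raise
    except (NoCandidateError, ValueError):
        return None
    if not is_admissible(sol).admissible:
        return None
    if params.model_family == "fourth_order":
        e = energy_E2_closed(sol, env)
    else:
        e = energy_E1_candidate(sol, env)
    if not math.isfinite(e):
        return None
    return sol, e


def _iterated_scan(f: Callable[[float], float], center: float, h: float,
                   r_floor: float, r_ceil: float, rounds: int = 3, pts: int = 101):
    """Successive local scans shrinking the window 50x per round.

    Robust when the minimum sits on the admissibility boundary (the
    objective jumps to +inf there), where gradient-style refinement can
    stall.  Final resolution ~ h / 50**rounds.
    """
    best_r, best_f = center, f(center)
    for _ in range(rounds):
        lo = max(center - h, r_floor)
        hi = min(center + h, r_ceil)
        for r in np.linspace(lo, hi, pts):
            fr = f(float(r))
            if fr < best_f:
                best_f, best_r = fr, float(r)
        center = best_r
        h = (hi - lo) / (pts - 1)
    return best_r, best_f


def minimise_energy(
    params: ModelParams,
    env: SingleClumpEnvironment,
    r_steps: int = 1000,
    r_min: float | None = None,
    r_max: float = 1.0,
) -> MinimisationResult:
    """Scan + refine the energy over the admissible half-widths.

    A uniform grid of ``r_steps`` points on ``(0, r_max]`` is scanned;
    inadmissible or singular half-widths are discarded; the best grid point
    is refined by iterated local scans to ``|dr| < 1e-6``.  Deterministic.
    """
    if params.gamma <= 1.0:
        raise RegimeError(f"energy minimisation requires gamma > 1, got gamma={params.gamma}")
    rs = np.linspace(r_max / r_steps if r_min is None else r_min, r_max, r_steps)
    best = None
    best_r = None
    for r in rs:
        try:
            out = _candidate_energy(params, env, float(r))
        except ResonanceError:
            raise
        if out is None:
            continue
        _, e = out
        if best is None or e < best:
            best, best_r = e, float(r)
    if best_r is None:
        raise NoMinimiserError("no admissible candidate at any scanned half-width")

    h = float(rs[1] - rs[0]) if len(rs) > 1 else best_r * 0.5

    cache: dict[float, tuple] = {}

    def objective(r: float) -> float:
        out = _candidate_energy(params, env, r)
        if out is None:
            return math.inf
        cache[r] = out
        return out[1]

    r_star, _ = _iterated_scan(objective, best_r, h, r_floor=1e-9, r_ceil=r_max)
    sol, e = cache[r_star]
    return MinimisationResult(r=r_star, solution=sol, energy=e)


def energy_curve(
    params: ModelParams,
    env: SingleClumpEnvironment,
    r_grid: np.ndarray,
) -> EnergyCurve:
    """E(r) over a user grid, keeping only admissible half-widths."""
    rs, es = [], []
    for r in np.asarray(r_grid, dtype=float):
        out = _candidate_energy(params, env, float(r))
        if out is None:
            continue
        rs.append(float(r))
        es.append(out[1])
    return EnergyCurve(np.array(rs), np.array(es))
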