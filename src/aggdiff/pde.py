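"""Explicit finite-volume time integration of the three model variants.

Schemes (all conservative, zero-flux boundaries, explicit Euler in time):

* ``quadratic_nonlocal`` -- ``u_t = d/dx ( u d/dx [ u - gamma K*u - A ] )``;
* ``quadratic_local4``   -- ``u_t = d/dx ( u d/dx [ (1-gamma) u
  - (gamma sigma^2/2) u'' - A ] )``;
* ``linear_nonlocal``    -- ``u_t = u_xx - d/dx [ u ( gamma d/dx(K*u) + A' ) ]``.

The advective flux is upwinded on the sign of the edge slope of the
potential, which keeps the quadratic schemes positivity-preserving under a
CFL-type step restriction.  Mass is conserved exactly (telescoping fluxes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import InstabilityError
from .kernels import Kernel, kernel_weights
from .landscape import Environment
from .steady_state import HomogeneousMinimiser, r0_of

__all__ = [
    "Grid",
    "SimState",
    "SolverConfig",
    "Diagnostics",
    "nondimensionalise",
    "dimensionalise",
    "total_mass",
    "make_initial_condition",
    "step",
    "run_to_steady",
]

Scheme = Literal["quadratic_nonlocal", "quadratic_local4", "linear_nonlocal"]

try:  # optional fast path for the inner loop; the numpy route is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred mesh on [x_min, x_max]."""

    x_min: float = -1.0
    x_max: float = 1.0
    dx: float = 0.01

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        n = (self.x_max - self.x_min) / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(x_max - x_min)/dx = {n} is not an integer cell count"
            )

    @property
    def n_cells(self) -> int:
        return int(round((self.x_max - self.x_min) / self.dx))

    @property
    def centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cells) + 0.5) * self.dx


@dataclass
class SimState:
    """Gridded density with time and bookkeeping diagnostics."""

    u: np.ndarray
    t: float
    grid: Grid
    clipped_mass: float = 0.0

    @property
    def mass(self) -> float:
        return total_mass(self.u, self.grid.dx)


@dataclass
class SolverConfig:
    scheme: Scheme
    gamma: float
    env: Environment
    sigma: float | None = None      # quadratic_local4
    kernel: Kernel | None = None    # nonlocal schemes
    dt: float = 5e-6
    tol: float = 1e-8
    max_time: float = 10.0
    cfl_safety: float = 0.4
    record_every: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tol <= 0:
            raise ValueError("dt and tol must be positive")
        if self.scheme == "quadratic_local4":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("quadratic_local4 requires sigma > 0")
        elif self.scheme in ("quadratic_nonlocal", "linear_nonlocal"):
            if self.kernel is None:
                raise ValueError(f"{self.scheme} requires a kernel")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class Diagnostics:
    converged: bool
    reason: str
    steps: int
    times: list[float] = field(default_factory=list)
    masses: list[float] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    max_delta: list[float] = field(default_factory=list)
    clipped_mass: float = 0.0


# --------------------------------------------------------------------------
# nondimensionalisation

_SCALINGS = {
    # name: (forward, inverse) given D, L
    "x": (lambda v, D, L: v / L, lambda v, D, L: v * L),
    "sigma": (lambda v, D, L: v / L, lambda v, D, L: v * L),
    "gamma": (lambda v, D, L: v / D, lambda v, D, L: v * D),
    "a": (lambda v, D, L: L * v / D, lambda v, D, L: D * v / L),
    "b": (lambda v, D, L: L * v / D, lambda v, D, L: D * v / L),
    "t": (lambda v, D, L: v * D / L**3, lambda v, D, L: v * L**3 / D),
    "u": (lambda v, D, L: L * v, lambda v, D, L: v / L),
    "m": (lambda v, D, L: v * L, lambda v, D, L: v / L),
}


def nondimensionalise(D: float, L: float, **quantities) -> dict:
    """Map dimensional quantities onto the unit half-period domain.

    Accepted keyword names: ``x, sigma, gamma, a, b, t, u, m`` (scalars or
    arrays; ``a``/``b`` are environment Fourier coefficients).  The map is
    invertible via :func:`dimensionalise`.
    """
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    out = {}
    for name, value in quantities.items():
        if name not in _SCALINGS:
            raise ValueError(f"unknown quantity {name!r}")
        out[name] = _SCALINGS[name][0](np.asarray(value, dtype=float), D, L)
        if np.ndim(value) == 0:
            out[name] = float(out[name])
    return out


def dimensionalise(D: float, L: float, **quantities) -> dict:
    """Inverse of :func:`nondimensionalise`."""
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    out = {}
    for name, value in quantities.items():
        if name not in _SCALINGS:
            raise ValueError(f"unknown quantity {name!r}")
        out[name] = _SCALINGS[name][1](np.asarray(value, dtype=float), D, L)
        if np.ndim(value) == 0:
            out[name] = float(out[name])
    return out


def total_mass(u: np.ndarray, dx: float) -> float:
    """Midpoint-rule mass, the exact invariant of the conservative scheme."""
    return float(np.sum(u) * dx)


# --------------------------------------------------------------------------
# initial conditions

def make_initial_condition(kind: str, grid: Grid, p: float = 1.0,
                           gamma: float | None = None, sigma: float | None = None,
                           mean: float = 0.5, sd: float = 0.05) -> np.ndarray:
    """Named initial-condition fixtures, normalised to total mass ``p``.

    ``eq30``     the flat-landscape minimum-energy lobe (needs gamma, sigma);
    ``gaussian`` an offset Gaussian (default mean 0.5, sd 0.05);
    ``eq40``     ``1 - cos(4 pi x)`` on ``|x| < 1/2`` (two bumps);
    ``eq41``     ``1 + cos(6 pi x)`` on ``|x| < 1/2`` (three bumps).
    """
    x = grid.centers
    if kind == "eq30":
        if gamma is None or sigma is None:
            raise ValueError("eq30 needs gamma and sigma")
        prof = HomogeneousMinimiser(r0=r0_of(gamma, sigma), p=p)
        u = prof.value(x)
    elif kind == "gaussian":
        u = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    elif kind == "eq40":
        u = np.where(np.abs(x) < 0.5, 1.0 - np.cos(4.0 * np.pi * x), 0.0)
    elif kind == "eq41":
        u = np.where(np.abs(x) < 0.5, 1.0 + np.cos(6.0 * np.pi * x), 0.0)
    else:
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    current = total_mass(u, grid.dx)
    if current <= 0:
        raise ValueError("initial condition has non-positive mass on this grid")
    return u * (p / current)


# --------------------------------------------------------------------------
# stepping

class _Workspace:
    """Per-run precomputation: environment samples and kernel weights."""

    def __init__(self, config: SolverConfig, grid: Grid):
        self.config = config
        self.grid = grid
        x = grid.centers
        self.A = np.asarray(config.env.value(x), dtype=float)
        self.weights = None
        if config.kernel is not None:
            self.weights = kernel_weights(config.kernel, grid.dx)
            self._pad = (len(self.weights) - 1) // 2
        self.warned_cfl = False

    def convolve(self, u: np.ndarray) -> np.ndarray:
        J = self._pad
        padded = np.concatenate([np.zeros(J), u, np.zeros(J)])
        return np.convolve(padded, self.weights, mode="valid")

    def second_diff(self, u: np.ndarray) -> np.ndarray:
        """Centred second difference with zero-gradient (ghost = edge) closure."""
        dx2 = self.grid.dx**2
        out = np.empty_like(u)
        out[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / dx2
        out[0] = (u[1] - u[0]) / dx2
        out[-1] = (u[-2] - u[-1]) / dx2
        return out

    def potential(self, u: np.ndarray) -> np.ndarray:
        """The advected potential xi whose gradient drives the flux."""
        c = self.config
        if c.scheme == "quadratic_nonlocal":
            return u - c.gamma * self.convolve(u) - self.A
        if c.scheme == "quadratic_local4":
            return (1.0 - c.gamma) * u - 0.5 * c.gamma * c.sigma**2 * self.second_diff(u) - self.A
        # linear_nonlocal: only the advective part; diffusion handled separately
        return -(c.gamma * self.convolve(u) + self.A)


def _advance(u: np.ndarray, ws: _Workspace, dt: float) -> tuple[np.ndarray, float]:
    """One explicit step; returns (new u, clipped mass this step)."""
    c = ws.config
    dx = ws.grid.dx
    xi = ws.potential(u)
    s = np.diff(xi) / dx  # edge slopes, length N-1
    # upwind: mass is removed from the cell the flux drains
    upw = np.where(s > 0.0, u[1:], u[:-1])
    flux = upw * s
    if c.scheme == "linear_nonlocal":
        flux = flux + np.diff(u) / dx
    if not ws.warned_cfl:
        smax = float(np.max(np.abs(s))) if s.size else 0.0
        if smax > 0 and dt > c.cfl_safety * dx**2 / smax:
            warnings.warn(
                f"dt={dt:g} exceeds the stability guideline "
                f"{c.cfl_safety * dx**2 / smax:g} for the current potential slope",
                RuntimeWarning,
                stacklevel=3,
            )
            ws.warned_cfl = True
    div = np.empty_like(u)
    div[0] = flux[0]
    div[-1] = -flux[-1]
    div[1:-1] = flux[1:] - flux[:-1]
    new = u + (dt / dx) * div
    if np.any(~np.isfinite(new)):
        raise InstabilityError("NaN/Inf produced; reduce dt")
    clipped = 0.0
    neg = new < 0.0
    if np.any(neg):
        undershoot = -float(new[neg].sum()) * dx
        clipped = undershoot
        new[neg] = 0.0
        pos_mass = float(new.sum()) * dx
        if pos_mass > 0:
            # redistribute proportionally so the step stays exactly conservative
            new *= (pos_mass - undershoot) / pos_mass
    return new, clipped


@_njit(cache=True)
def _local4_chunk(u, A, dx, dt, gamma, half_gs2, n_steps, tol):  # pragma: no cover - numba
    """Run up to n_steps of the quadratic_local4 scheme in place.

    Replicates the numpy path's per-element arithmetic exactly.  Returns
    (steps done, last sup-norm change, clipped mass added).
    """
    N = u.shape[0]
    xi = np.empty(N)
    unew = np.empty(N)
    dx2 = dx * dx
    clipped = 0.0
    delta = 0.0
    for k in range(n_steps):
        xi[0] = (1.0 - gamma) * u[0] - half_gs2 * ((u[1] - u[0]) / dx2) - A[0]
        for i in range(1, N - 1):
            xi[i] = (1.0 - gamma) * u[i] - half_gs2 * ((u[i + 1] - 2.0 * u[i] + u[i - 1]) / dx2) - A[i]
        xi[N - 1] = (1.0 - gamma) * u[N - 1] - half_gs2 * ((u[N - 2] - u[N - 1]) / dx2) - A[N - 1]
        prev_flux = 0.0
        for i in range(N):
            if i < N - 1:
                s = (xi[i + 1] - xi[i]) / dx
                upw = u[i + 1] if s > 0.0 else u[i]
                flux = upw * s
            else:
                flux = 0.0
            unew[i] = u[i] + (dt / dx) * (flux - prev_flux)
            prev_flux = flux
        has_neg = False
        for i in range(N):
            if unew[i] < 0.0:
                has_neg = True
                break
        if has_neg:
            under = 0.0
            for i in range(N):
                if unew[i] < 0.0:
                    under -= unew[i]
                    unew[i] = 0.0
            under *= dx
            pos = 0.0
            for i in range(N):
                pos += unew[i]
            pos *= dx
            if pos > 0.0:
                fac = (pos - under) / pos
                for i in range(N):
                    unew[i] *= fac
            clipped += under
        delta = 0.0
        for i in range(N):
            d = abs(unew[i] - u[i])
            if d > delta:
                delta = d
            u[i] = unew[i]
        if delta < tol:
            return k + 1, delta, clipped
    return n_steps, delta, clipped


def step(state: SimState, config: SolverConfig, _workspace: _Workspace | None = None) -> SimState:
    """Advance one explicit time step, conserving mass exactly."""
    ws = _workspace or _Workspace(config, state.grid)
    new_u, clipped = _advance(state.u, ws, config.dt)
    return SimState(
        u=new_u,
        t=state.t + config.dt,
        grid=state.grid,
        clipped_mass=state.clipped_mass + clipped,
    )


def _discrete_energy(u: np.ndarray, ws: _Workspace) -> float:
    """The scheme's own Lyapunov functional on the grid.

    ``quadratic_local4`` uses E2, ``quadratic_nonlocal`` uses E1; the linear
    scheme uses the entropy form ``int [2 u ln u - 2 A u - gamma u K*u]``.
    All are non-increasing along the corresponding semi-discrete flow.
    """
    c = ws.config
    dx = ws.grid.dx
    if c.scheme == "quadratic_local4":
        integrand = u * ((1.0 - c.gamma) * u - 2.0 * ws.A
                         - 0.5 * c.gamma * c.sigma**2 * ws.second_diff(u))
    elif c.scheme == "quadratic_nonlocal":
        integrand = u * ((1.0 - c.gamma) * u - 2.0 * ws.A - c.gamma * ws.convolve(u))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ulogu = np.where(u > 0.0, u * np.log(np.where(u > 0.0, u, 1.0)), 0.0)
        integrand = 2.0 * ulogu - 2.0 * ws.A * u - c.gamma * u * ws.convolve(u)
    return float(np.sum(integrand) * dx)


def run_to_steady(state: SimState, config: SolverConfig) -> tuple[SimState, Diagnostics]:
    """Iterate until the per-step sup-norm change drops below ``config.tol``.

    Records mass, energy and max per-step change every ``record_every``
    steps.  Terminates with ``converged=False`` when ``max_time`` is
    reached first.  Raises :class:`InstabilityError` if cumulative clipped
    mass exceeds ``1e-8`` of the total.
    """
    ws = _Workspace(config, state.grid)
    u = state.u.copy()
    t = state.t
    dt = config.dt
    p = total_mass(u, state.grid.dx)
    clipped_total = state.clipped_mass
    diag = Diagnostics(converged=False, reason="max_time", steps=0)
    max_steps = int(math.ceil((config.max_time - t) / dt))
    record_every = max(1, config.record_every)

    diag.times.append(t)
    diag.masses.append(p)
    diag.energies.append(_discrete_energy(u, ws))
    diag.max_delta.append(math.nan)

    use_fast = _HAVE_NUMBA and config.scheme == "quadratic_local4"
    if use_fast:
        # trigger the one-off CFL advisory from the initial state
        _advance(u.copy(), ws, dt)
        half_gs2 = 0.5 * config.gamma * config.sigma**2
        done = 0
        while done < max_steps:
            chunk = min(record_every, max_steps - done)
            k, delta, clipped = _local4_chunk(
                u, ws.A, state.grid.dx, dt, config.gamma, half_gs2, chunk, config.tol
            )
            if not np.all(np.isfinite(u)):
                raise InstabilityError("NaN/Inf produced; reduce dt")
            clipped_total += clipped
            if clipped_total > 1e-8 * max(p, 1e-300):
                raise InstabilityError(
                    f"clipped mass {clipped_total:.3e} exceeds 1e-8 of total; reduce dt"
                )
            done += k
            t += k * dt
            diag.steps = done
            diag.times.append(t)
            diag.masses.append(total_mass(u, state.grid.dx))
            diag.energies.append(_discrete_energy(u, ws))
            diag.max_delta.append(float(delta))
            if delta < config.tol:
                diag.converged = True
                diag.reason = "steady"
                break
    else:
        for k in range(1, max_steps + 1):
            new_u, clipped = _advance(u, ws, dt)
            clipped_total += clipped
            if clipped_total > 1e-8 * max(p, 1e-300):
                raise InstabilityError(
                    f"clipped mass {clipped_total:.3e} exceeds 1e-8 of total; reduce dt"
                )
            delta = float(np.max(np.abs(new_u - u)))
            u = new_u
            t += dt
            diag.steps = k
            if k % record_every == 0:
                diag.times.append(t)
                diag.masses.append(total_mass(u, state.grid.dx))
                diag.energies.append(_discrete_energy(u, ws))
                diag.max_delta.append(delta)
            if delta < config.tol:
                diag.converged = True
                diag.reason = "steady"
                break

    if diag.times[-1] != t:
        diag.times.append(t)
        diag.masses.append(total_mass(u, state.grid.dx))
        diag.energies.append(_discrete_energy(u, ws))
    diag.clipped_mass = clipped_total
    final = SimState(u=u, t=t, grid=state.grid, clipped_mass=clipped_total)
    return final, diag
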