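"""Desk-scale validation: re-run every module's invariant checks and report."""

from __future__ import annotations

import numpy as np

from ..energy import energy_E2_closed, energy_E2_quadrature, minimise_energy
from ..errors import NoCandidateError, ResonanceError
from ..kernels import LaplaceKernel, TopHatKernel, convolve, kernel_std
from ..landscape import SingleClumpEnvironment, TwoClumpEnvironment, make_fourier
from ..pde import Grid, SimState, SolverConfig, make_initial_condition, run_to_steady, total_mass
from ..steady_state import ModelParams, build_candidate, is_admissible, r0_of, steady_residual

__all__ = ["validate_all"]


def _check(report: dict, name: str, measured: float, tolerance: float, larger_ok: bool = False) -> None:
    passed = measured <= tolerance if not larger_ok else measured >= tolerance
    report[name] = {
        "passed": bool(passed),
        "tolerance": tolerance,
        "measured": float(measured),
    }


def validate_all(include_pde: bool = False, seed: int = 0) -> dict:
    """Execute the analytic invariant suite (and optionally a small PDE suite).

    Returns a report mapping check name to {passed, tolerance, measured};
    failures are entries, not exceptions.
    """
    rng = np.random.default_rng(seed)
    report: dict = {}

    # landscape evenness
    xs = np.linspace(-1.0, 1.0, 1001)
    for env, name in [
        (SingleClumpEnvironment(n=3, amplitude=2.0), "clump"),
        (TwoClumpEnvironment(amplitude=1.5), "two_clump"),
    ]:
        _check(report, f"landscape_evenness_{name}",
               float(np.abs(env.value(xs) - env.value(-xs)).max()), 0.0)

    # Fourier round-trip
    env = SingleClumpEnvironment(n=4, amplitude=1.0)
    four = make_fourier(env, 64)
    grid = np.linspace(-1.0, 1.0, 512)
    _check(report, "fourier_roundtrip",
           float(np.abs(four.value(grid) - env.value(grid)).max()), 1e-3)

    # kernel normalisation under convolution
    dx = 0.005
    x = np.arange(-1 + dx / 2, 1, dx)
    ones = np.ones_like(x)
    # unity tolerance reflects the zero-extension tail: exact for the compact
    # top-hat, exponentially small (m=40, depth 0.5 -> ~1e-9) for Laplace
    for kern, name, tol in [(LaplaceKernel(40.0), "laplace", 1e-8),
                            (TopHatKernel(0.1), "tophat", 1e-10)]:
        conv = convolve(kern, ones, dx)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        _check(report, f"kernel_interior_unity_{name}",
               float(np.abs(conv[mid] - 1.0).max()), tol)
        _check(report, f"kernel_std_positive_{name}", kernel_std(kern), 0.0, larger_ok=True)

    # proposition fidelity on random draws (exact-branch half-widths)
    worst_res, worst_mass, worst_edge = 0.0, 0.0, 0.0
    draws = 0
    while draws < 20:
        gamma = rng.uniform(1.2, 5.0)
        sigma = rng.uniform(0.05, 0.3)
        n = int(rng.integers(1, 17))
        a_n = rng.uniform(0.0, 10.0)
        params = ModelParams(gamma=gamma, sigma=sigma, p=1.0)
        envd = SingleClumpEnvironment(n=n, amplitude=a_n)
        r = rng.uniform(0.02, 1.0 / n)
        try:
            sol = build_candidate(params, envd, r)
        except (NoCandidateError, ResonanceError):
            continue
        draws += 1
        worst_res = max(worst_res, steady_residual(sol))
        worst_mass = max(worst_mass, abs(sol.mass() - 1.0))
        worst_edge = max(worst_edge, abs(float(sol.value(r))))
    _check(report, "candidate_ode_residual", worst_res, 1e-8)
    _check(report, "candidate_mass", worst_mass, 1e-10)
    _check(report, "candidate_vanishes_at_edge", worst_edge, 1e-10)

    # closed-form vs quadrature energy
    worst = 0.0
    done = 0
    while done < 10:
        gamma = rng.uniform(1.5, 4.0)
        sigma = rng.uniform(0.05, 0.2)
        n = int(rng.integers(1, 9))
        params = ModelParams(gamma=gamma, sigma=sigma, p=1.0)
        envd = SingleClumpEnvironment(n=n, amplitude=rng.uniform(0.0, 5.0))
        r = rng.uniform(0.05, min(1.0, 2.0 / n))
        try:
            sol = build_candidate(params, envd, r)
        except (NoCandidateError, ResonanceError):
            continue
        done += 1
        e_closed = energy_E2_closed(sol, envd)
        e_quad = energy_E2_quadrature(sol, envd, gamma, sigma)
        worst = max(worst, abs(e_closed - e_quad))
    _check(report, "energy_closed_vs_quadrature", worst, 1e-6)

    # homogeneous recovery
    params = ModelParams(gamma=2.0, sigma=0.1, p=1.0)
    res = minimise_energy(params, SingleClumpEnvironment(n=1, amplitude=0.0))
    _check(report, "homogeneous_r0_recovery", abs(res.r - r0_of(2.0, 0.1)), 1e-6)

    if include_pde:
        g = Grid(dx=0.02)
        envp = SingleClumpEnvironment(n=1, amplitude=1.0)
        u0 = make_initial_condition("eq30", g, p=1.0, gamma=2.0, sigma=0.1)
        cfg = SolverConfig(scheme="quadratic_local4", gamma=2.0, sigma=0.1,
                           env=envp, dt=4e-7, tol=1e-8, max_time=0.02)
        final, diag = run_to_steady(SimState(u=u0, t=0.0, grid=g), cfg)
        _check(report, "pde_mass_drift",
               float(np.abs(np.array(diag.masses) - 1.0).max()), 1e-12)
        _check(report, "pde_positivity", -float(final.u.min()), 1e-12)
        energy_steps = np.diff(np.array(diag.energies))
        _check(report, "pde_energy_nonincreasing",
               float(energy_steps.max()) if len(energy_steps) else 0.0,
               1e-10 * max(1, cfg.record_every))
        _check(report, "pde_final_mass", abs(total_mass(final.u, g.dx) - 1.0), 1e-12)

    return report
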