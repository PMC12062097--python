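"""Command-line interface: minimise, energy-curve, simulate, sweep, validate."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import click
import numpy as np

from ..energy import energy_curve, minimise_energy
from ..kernels import LaplaceKernel, TopHatKernel
from ..landscape import SingleClumpEnvironment, TwoClumpEnvironment
from ..metrics import sweep as run_sweep
from ..pde import Grid, SimState, SolverConfig, make_initial_condition, run_to_steady
from ..steady_state import ModelParams
from .config import RunConfig, load_config
from .io import write_profile
from .validate import validate_all


def _merged_config(config_path, **overrides) -> RunConfig:
    cfg = load_config(config_path) if config_path else RunConfig()
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    return cfg


def _params_from(cfg: RunConfig) -> ModelParams:
    family = "laplace" if cfg.model == "laplace" else "fourth_order"
    return ModelParams(
        gamma=cfg.gamma, p=cfg.p, model_family=family,
        sigma=cfg.sigma if family == "fourth_order" else None,
        m=cfg.m if family == "laplace" else None,
    )


@click.group()
def main() -> None:
    """Aggregation-diffusion toolkit for heterogeneous 1-D environments."""


_common = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None),
    click.option("--model", type=click.Choice(["fourth_order", "laplace", "linear"]), default=None),
    click.option("--gamma", type=float, default=None),
    click.option("--sigma", type=float, default=None),
    click.option("--m", type=float, default=None),
    click.option("--p", type=float, default=None),
    click.option("--n", "n_mode", type=int, default=None),
    click.option("--amplitude", type=float, default=None),
]


def _add_options(options):
    def wrap(fn):
        for opt in reversed(options):
            fn = opt(fn)
        return fn
    return wrap


@main.command()
@_add_options(_common)
@click.option("--profile-out", type=click.Path(), default=None,
              help="optional CSV of the minimising profile")
def minimise(config_path, model, gamma, sigma, m, p, n_mode, amplitude, profile_out):
    """Minimise the energy over the aggregation half-width."""
    cfg = _merged_config(config_path, model=model, gamma=gamma, sigma=sigma, m=m, p=p)
    env = cfg.environment if isinstance(cfg.environment, SingleClumpEnvironment) else None
    env = SingleClumpEnvironment(
        n=n_mode if n_mode is not None else (env.n if env else 1),
        amplitude=amplitude if amplitude is not None else (env.amplitude if env else 1.0),
    )
    params = _params_from(cfg)
    res = minimise_energy(params, env)
    record = res.solution.as_dict()
    record["energy"] = res.energy
    click.echo(json.dumps(record, indent=2))
    if profile_out:
        xs = np.linspace(-1.0, 1.0, 2001)
        write_profile(xs, res.solution.value(xs), profile_out, parameters=record)


@main.command("energy-curve")
@_add_options(_common)
@click.option("--r-min", type=float, default=0.01)
@click.option("--r-max", type=float, default=1.0)
@click.option("--r-steps", type=int, default=200)
@click.option("--out", type=click.Path(), default=None)
def energy_curve_cmd(config_path, model, gamma, sigma, m, p, n_mode, amplitude,
                     r_min, r_max, r_steps, out):
    """Tabulate E(r) over admissible half-widths (CSV: r,E)."""
    cfg = _merged_config(config_path, model=model, gamma=gamma, sigma=sigma, m=m, p=p)
    env = SingleClumpEnvironment(n=n_mode or 1, amplitude=1.0 if amplitude is None else amplitude)
    params = _params_from(cfg)
    curve = energy_curve(params, env, np.linspace(r_min, r_max, r_steps))
    lines = ["r,E"] + [f"{r:.10g},{e:.10g}" for r, e in zip(curve.r_values, curve.energies)]
    text = "\n".join(lines) + "\n"
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text, nl=False)
    if curve.empty:
        click.echo("# no admissible half-widths", err=True)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--scheme", type=click.Choice(
    ["quadratic_local4", "quadratic_nonlocal", "linear_nonlocal"]), default=None)
@click.option("--kernel", "kernel_name", type=click.Choice(["laplace", "tophat"]), default=None)
@click.option("--gamma", type=float, default=None)
@click.option("--sigma", type=float, default=None)
@click.option("--m", type=float, default=None)
@click.option("--delta", type=float, default=None)
@click.option("--env-type", type=click.Choice(["clump", "two_clump"]), default=None)
@click.option("--n", "n_mode", type=int, default=None)
@click.option("--amplitude", type=float, default=None)
@click.option("--p", type=float, default=None)
@click.option("--ic", type=click.Choice(["eq30", "gaussian", "eq40", "eq41"]), default=None)
@click.option("--dx", type=float, default=None)
@click.option("--dt", type=float, default=None)
@click.option("--tol", type=float, default=None)
@click.option("--max-time", type=float, default=None)
@click.option("--out", type=click.Path(), default=None, help="profile CSV")
@click.option("--log", "log_path", type=click.Path(), default=None, help="diagnostics JSON")
def simulate(config_path, scheme, kernel_name, gamma, sigma, m, delta, env_type,
             n_mode, amplitude, p, ic, dx, dt, tol, max_time, out, log_path):
    """Integrate the selected PDE to steady state."""
    cfg = _merged_config(config_path, scheme=scheme, gamma=gamma, sigma=sigma, m=m,
                         delta=delta, p=p, ic=ic, dx=dx, dt=dt, tol=tol, max_time=max_time)
    if env_type == "two_clump" or (env_type is None and isinstance(cfg.environment, TwoClumpEnvironment)):
        env = TwoClumpEnvironment(amplitude=amplitude if amplitude is not None else 1.0)
    else:
        base = cfg.environment if isinstance(cfg.environment, SingleClumpEnvironment) else None
        env = SingleClumpEnvironment(
            n=n_mode if n_mode is not None else (base.n if base else 1),
            amplitude=amplitude if amplitude is not None else (base.amplitude if base else 1.0),
        )
    kernel = cfg.kernel
    if kernel_name == "laplace":
        kernel = LaplaceKernel(rate=cfg.m if cfg.m else 10.0)
    elif kernel_name == "tophat":
        kernel = TopHatKernel(half_width=cfg.delta if cfg.delta else 0.1)
    grid = Grid(dx=cfg.dx)
    u0 = make_initial_condition(cfg.ic, grid, p=cfg.p, gamma=cfg.gamma, sigma=cfg.sigma)
    solver = SolverConfig(scheme=cfg.scheme, gamma=cfg.gamma, sigma=cfg.sigma,
                          kernel=kernel, env=env, dt=cfg.dt, tol=cfg.tol,
                          max_time=cfg.max_time)
    final, diag = run_to_steady(SimState(u=u0, t=0.0, grid=grid), solver)
    summary = {
        "converged": diag.converged,
        "reason": diag.reason,
        "steps": diag.steps,
        "t_final": final.t,
        "mass": final.mass,
        "clipped_mass": diag.clipped_mass,
    }
    click.echo(json.dumps(summary, indent=2))
    if out:
        write_profile(grid.centers, final.u, out, parameters={
            "scheme": cfg.scheme, "gamma": cfg.gamma, "sigma": cfg.sigma,
            "p": cfg.p, "dx": cfg.dx, "dt": cfg.dt, "ic": cfg.ic,
        })
    if log_path:
        Path(log_path).write_text(json.dumps({
            **summary,
            "times": diag.times,
            "masses": diag.masses,
            "energies": diag.energies,
            "max_delta": diag.max_delta,
        }, indent=2))


@main.command("sweep")
@_add_options(_common)
@click.option("--parameter", required=True,
              type=click.Choice(["n", "amplitude", "gamma", "sigma", "p"]))
@click.option("--values", required=True, help="comma-separated values")
@click.option("--method", type=click.Choice(["analytic", "pde"]), default="analytic")
@click.option("--out", type=click.Path(), default=None, help="CSV table")
@click.option("--summary-out", type=click.Path(), default=None, help="JSON summary")
def sweep_cmd(config_path, model, gamma, sigma, m, p, n_mode, amplitude,
              parameter, values, method, out, summary_out):
    """Sweep one parameter, recording the minimiser geometry per value."""
    cfg = _merged_config(config_path, model=model, gamma=gamma, sigma=sigma, m=m, p=p)
    env = SingleClumpEnvironment(n=n_mode or 1, amplitude=1.0 if amplitude is None else amplitude)
    params = _params_from(cfg)
    vals = [float(v) for v in values.split(",")]
    table = run_sweep(params, env, parameter, vals, method=method)
    df = table.to_dataframe()
    if out:
        df.to_csv(out, index=False)
    else:
        click.echo(df.to_csv(index=False), nl=False)
    summary = {
        "argmin_width": None if np.all(np.isnan(table.widths))
        else float(table.values[int(np.nanargmin(table.widths))]),
        "argmax_peak": None if np.all(np.isnan(table.peak_heights))
        else float(table.values[int(np.nanargmax(table.peak_heights))]),
        "width_monotone_nonincreasing": bool(np.all(np.diff(table.widths[~np.isnan(table.widths)]) <= 1e-12)),
        "failures": table.failures,
    }
    if summary_out:
        Path(summary_out).write_text(json.dumps(summary, indent=2))
    else:
        click.echo(json.dumps(summary, indent=2))


@main.command()
@click.option("--include-pde", is_flag=True, default=False)
@click.option("--out", type=click.Path(), default=None)
def validate(include_pde, out):
    """Run the module invariant suites and emit a pass/fail report."""
    report = validate_all(include_pde=include_pde)
    text = json.dumps(report, indent=2)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text)
    if not all(entry["passed"] for entry in report.values()):
        sys.exit(1)


if __name__ == "__main__":
    main()
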