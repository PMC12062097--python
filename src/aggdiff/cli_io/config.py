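"""Run configuration: schema-validated YAML/JSON with logged defaults."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..kernels import Kernel, LaplaceKernel, TopHatKernel
from ..landscape import (
    Environment,
    FourierEnvironment,
    SingleClumpEnvironment,
    TwoClumpEnvironment,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_config", "dump_config"]

logger = logging.getLogger("aggdiff.config")


class ConfigError(ValueError):
    """A configuration violates the schema."""


_DEFAULTS = {
    "model": "fourth_order",
    "scheme": "quadratic_local4",
    "gamma": 2.0,
    "sigma": 0.1,
    "m": None,
    "delta": None,
    "p": 1.0,
    "dx": 0.01,
    "dt": 5e-6,
    "tol": 1e-8,
    "max_time": 10.0,
    "ic": "eq30",
    "seed": None,
    "out": None,
    "log": None,
}

_TOP_KEYS = set(_DEFAULTS) | {"environment", "kernel"}
_ENV_KEYS = {"type", "n", "amplitude", "a0", "coeffs", "sine_coeffs"}
_KERNEL_KEYS = {"kernel", "m", "delta"}

_MODELS = {"fourth_order", "laplace", "linear"}
_SCHEMES = {"quadratic_local4", "quadratic_nonlocal", "linear_nonlocal"}
_ICS = {"eq30", "gaussian", "eq40", "eq41"}


@dataclass
class RunConfig:
    model: str = "fourth_order"
    scheme: str = "quadratic_local4"
    environment: Environment | None = None
    kernel: Kernel | None = None
    gamma: float = 2.0
    sigma: float | None = 0.1
    m: float | None = None
    delta: float | None = None
    p: float = 1.0
    dx: float = 0.01
    dt: float = 5e-6
    tol: float = 1e-8
    max_time: float = 10.0
    ic: str = "eq30"
    seed: int | None = None
    out: str | None = None
    log: str | None = None
    applied_defaults: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "scheme": self.scheme,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "m": self.m,
            "delta": self.delta,
            "p": self.p,
            "dx": self.dx,
            "dt": self.dt,
            "tol": self.tol,
            "max_time": self.max_time,
            "ic": self.ic,
            "seed": self.seed,
            "out": self.out,
            "log": self.log,
        }
        if self.environment is not None:
            d["environment"] = _env_to_dict(self.environment)
        if self.kernel is not None:
            d["kernel"] = _kernel_to_dict(self.kernel)
        return {k: v for k, v in d.items() if v is not None}


def _env_to_dict(env: Environment) -> dict:
    if isinstance(env, SingleClumpEnvironment):
        return {"type": "clump", "n": env.n, "amplitude": env.amplitude}
    if isinstance(env, TwoClumpEnvironment):
        return {"type": "two_clump", "amplitude": env.amplitude}
    return {
        "type": "fourier",
        "a0": env.a0,
        "coeffs": list(env.cosine_coeffs),
        "sine_coeffs": list(env.sine_coeffs),
    }


def _kernel_to_dict(kernel: Kernel) -> dict:
    if isinstance(kernel, LaplaceKernel):
        return {"kernel": "laplace", "m": kernel.rate}
    return {"kernel": "tophat", "delta": kernel.half_width}


def _parse_environment(block: dict) -> Environment:
    unknown = set(block) - _ENV_KEYS
    if unknown:
        raise ConfigError(f"unknown environment keys: {sorted(unknown)}")
    etype = block.get("type")
    if etype == "clump":
        return SingleClumpEnvironment(n=int(block.get("n", 1)), amplitude=float(block.get("amplitude", 1.0)))
    if etype == "two_clump":
        return TwoClumpEnvironment(amplitude=float(block.get("amplitude", 1.0)))
    if etype == "fourier":
        return FourierEnvironment(
            a0=float(block.get("a0", 0.0)),
            cosine_coeffs=tuple(block.get("coeffs", ())),
            sine_coeffs=tuple(block.get("sine_coeffs", ())),
        )
    raise ConfigError(f"unknown environment type {etype!r}")


def _parse_kernel(block: dict) -> Kernel:
    unknown = set(block) - _KERNEL_KEYS
    if unknown:
        raise ConfigError(f"unknown kernel keys: {sorted(unknown)}")
    ktype = block.get("kernel")
    if ktype == "laplace":
        return LaplaceKernel(rate=float(block["m"]))
    if ktype == "tophat":
        return TopHatKernel(half_width=float(block["delta"]))
    raise ConfigError(f"unknown kernel type {ktype!r}")


def parse_config(raw: dict) -> RunConfig:
    """Validate a raw mapping, apply (and log) documented defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    applied = []
    merged = dict(_DEFAULTS)
    for key, value in raw.items():
        if key in ("environment", "kernel"):
            continue
        merged[key] = value
    for key, default in _DEFAULTS.items():
        if key not in raw and default is not None:
            applied.append(f"{key}={default}")
            logger.debug("config default applied: %s=%r", key, default)

    if merged["model"] not in _MODELS:
        raise ConfigError(f"model must be one of {sorted(_MODELS)}, got {merged['model']!r}")
    if merged["scheme"] not in _SCHEMES:
        raise ConfigError(f"scheme must be one of {sorted(_SCHEMES)}, got {merged['scheme']!r}")
    if merged["ic"] not in _ICS:
        raise ConfigError(f"ic must be one of {sorted(_ICS)}, got {merged['ic']!r}")
    for key in ("gamma", "p", "dx", "dt", "tol", "max_time"):
        if float(merged[key]) <= 0:
            raise ConfigError(f"{key} must be positive, got {merged[key]}")
    for key in ("sigma", "m", "delta"):
        if merged[key] is not None and float(merged[key]) <= 0:
            raise ConfigError(f"{key} must be positive when given, got {merged[key]}")

    env = _parse_environment(raw["environment"]) if "environment" in raw else None
    kernel = _parse_kernel(raw["kernel"]) if "kernel" in raw else None

    return RunConfig(
        model=merged["model"],
        scheme=merged["scheme"],
        environment=env,
        kernel=kernel,
        gamma=float(merged["gamma"]),
        sigma=None if merged["sigma"] is None else float(merged["sigma"]),
        m=None if merged["m"] is None else float(merged["m"]),
        delta=None if merged["delta"] is None else float(merged["delta"]),
        p=float(merged["p"]),
        dx=float(merged["dx"]),
        dt=float(merged["dt"]),
        tol=float(merged["tol"]),
        max_time=float(merged["max_time"]),
        ic=merged["ic"],
        seed=None if merged["seed"] is None else int(merged["seed"]),
        out=merged["out"],
        log=merged["log"],
        applied_defaults=applied,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return parse_config(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out (YAML); loadable by :func:`load_config`."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
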