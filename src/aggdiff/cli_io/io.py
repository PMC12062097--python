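"""Profile export/import as two-column delimited text."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .. import __version__

__all__ = ["write_profile", "read_profile"]


def write_profile(x, u, path, parameters: dict | None = None) -> None:
    """Write (x, u) as CSV with a header comment recording the parameters.

    Re-exporting identical inputs produces a bit-identical file.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != u.shape:
        raise ValueError("x and u must have the same shape")
    lines = [f"# aggdiff {__version__}"]
    for key in sorted(parameters or {}):
        lines.append(f"# {key} = {parameters[key]!r}")
    lines.append("# x,u")
    for xi, ui in zip(x, u):
        lines.append(f"{xi:.17g},{ui:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Inverse of :func:`write_profile`; returns (x, u, parameters)."""
    params: dict = {}
    xs, us = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if " = " in body:
                key, _, value = body.partition(" = ")
                try:
                    params[key.strip()] = eval(value, {"__builtins__": {}}, {})  # noqa: S307
                except Exception:
                    params[key.strip()] = value
            continue
        if not line.strip():
            continue
        a, b = line.split(",")
        xs.append(float(a))
        us.append(float(b))
    return np.array(xs), np.array(us), params
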