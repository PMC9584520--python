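"""Configuration loading, fixtures, seeding and run manifests.

The package ships two parameter files: the uniform prior table for the
three-strain community models and the fixed "chaotic input vector" used by
the sensitivity, scan and steady-state analyses.  Both are YAML and can be
replaced by user files of the same shape.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .dynamics import GLVParams, Termination, Trajectory, simulate

__all__ = [
    "load_prior_config",
    "load_fixed_params",
    "load_glv_attractor",
    "make_fixture",
    "RunManifest",
    "derive_seed",
]

_DATA = resources.files("chaoscope") / "data"


def _read_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        with resources.as_file(_DATA / default_name) as p:
            return yaml.safe_load(p.read_text())
    return yaml.safe_load(Path(path).read_text())


def load_prior_config(path: str | Path | None = None) -> dict:
    """Load and validate a prior-bounds table.

    Returns ``{"parameters": {name: {min, max, scale}}, "initial_state": ...}``
    with every ``min <= max``.  Constants are rows with ``min == max``.
    """
    raw = _read_yaml(path, "priors_three_strain.yaml")
    for section in ("parameters", "initial_state"):
        if section not in raw:
            raise ValueError(f"prior config missing section {section!r}")
        for name, row in raw[section].items():
            if "min" not in row or "max" not in row:
                raise ValueError(f"prior row {name!r} missing min/max")
            if row["min"] > row["max"]:
                raise ValueError(f"prior row {name!r} has min > max")
            row.setdefault("scale", "linear")
    return raw


def load_fixed_params(path: str | Path | None = None) -> tuple[dict, dict]:
    """Load a fixed parameter vector plus initial state.

    Returns ``(parameters, initial_state)`` as flat name->float mappings.
    """
    raw = _read_yaml(path, "chaotic_point.yaml")
    params = {k: float(v) for k, v in raw["parameters"].items()}
    init = {k: float(v) for k, v in raw["initial_state"].items()}
    return params, init


def load_glv_attractor(path: str | Path | None = None) -> tuple[GLVParams, np.ndarray]:
    """Load the four-species competitive gLV chaotic-attractor benchmark."""
    raw = _read_yaml(path, "glv_chaotic_attractor.yaml")
    params = GLVParams(r=np.array(raw["r"], dtype=float),
                       alpha=np.array(raw["alpha"], dtype=float))
    return params, np.array(raw["initial_state"], dtype=float)


# ---------------------------------------------------------------------------
# Synthetic test signals
# ---------------------------------------------------------------------------

def make_fixture(name: str, params: Mapping[str, float] | None = None,
                 seed: int | None = None) -> Trajectory:
    """Generate a synthetic signal with known analytic properties.

    Available fixtures: ``sine``, ``damped_sine``, ``multi_tone``,
    ``constant`` (single-channel, uniform 1 h grid over 5000 h by default)
    and ``lorenz`` (three-channel chaotic benchmark).  Each trajectory's
    ``meta`` records the generator parameters.
    """
    p = dict(params or {})
    t_end = float(p.pop("t_end", 5000.0))
    dt = float(p.pop("dt", 1.0))
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    meta = {"fixture": name, "dt": dt, **p}

    if name == "sine":
        period = float(p.get("period", 100.0))
        amp = float(p.get("amplitude", 0.2))
        offset = float(p.get("offset", 0.5))
        y = offset + amp * np.sin(2 * np.pi * t / period)
        states = y[:, None]
        names = ("signal",)
    elif name == "damped_sine":
        period = float(p.get("period", 100.0))
        amp = float(p.get("amplitude", 0.2))
        decay = float(p.get("decay", 1e-3))
        offset = float(p.get("offset", 0.5))
        y = offset + amp * np.exp(-decay * t) * np.sin(2 * np.pi * t / period)
        states = y[:, None]
        names = ("signal",)
    elif name == "multi_tone":
        periods = p.get("periods", (100.0, 500.0))
        amps = p.get("amplitudes", (1.0, 3.0))
        offset = float(p.get("offset", 5.0))
        y = offset + sum(a * np.sin(2 * np.pi * t / T) for a, T in zip(amps, periods))
        states = np.asarray(y)[:, None]
        names = ("signal",)
    elif name == "constant":
        value = float(p.get("value", 0.3))
        states = np.full((t.size, 1), value)
        names = ("signal",)
    elif name == "lorenz":
        sigma = float(p.get("sigma", 10.0))
        rho = float(p.get("rho", 28.0))
        beta = float(p.get("beta", 8.0 / 3.0))
        y0 = np.asarray(p.get("y0", (1.0, 1.0, 1.0)), dtype=float)

        def rhs(tt, y):
            x, yy, z = y
            return np.array([sigma * (yy - x), x * (rho - z) - yy, x * yy - beta * z])

        traj = simulate(rhs, np.abs(y0), t_end=t_end, dt_out=dt,
                        extinction_threshold=None, state_names=("x", "y", "z"),
                        rtol=1e-9, atol=1e-12, method="RK45")
        traj.meta.update(meta)
        return traj
    else:
        raise ValueError(f"unknown fixture {name!r}")

    return Trajectory(times=t, states=states, termination=Termination("completed"),
                      state_names=names, meta=meta)


# ---------------------------------------------------------------------------
# Seeding and manifests
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *context: object) -> int:
    """Deterministically derive a sub-seed (< 2**31) from a master seed."""
    h = hashlib.sha256(repr((int(master_seed),) + tuple(context)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


@dataclass
class RunManifest:
    """Record of a run sufficient to reproduce it bit-compatibly."""

    tool_version: str
    master_seed: int
    settings: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)   # path -> sha256

    def add_file(self, path: str | Path) -> None:
        path = Path(path)
        self.files[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "tool_version": self.tool_version,
            "master_seed": self.master_seed,
            "settings": self.settings,
            "files": self.files,
        }, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(tool_version=raw["tool_version"], master_seed=raw["master_seed"],
                   settings=raw.get("settings", {}), files=raw.get("files", {}))
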