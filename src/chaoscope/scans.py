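"""Parameter-plane maps, bifurcation diagrams, sensitivity maps and ramps.

All scans start from a single *input vector* — a flat mapping holding both
the model parameters (``D``, ``kA_1``, ``mu_max_x``, ...) and the initial
state (``N_x``, ``S``, ``B_z``, ``A_y``) — override one or two entries per
grid cell, re-simulate, estimate the maximal Lyapunov exponent, and
classify the dynamics as stable / oscillatory / chaotic / extinct.

Real-time ramps instead integrate a single trajectory while a parameter
(the dilution rate or a QS production rate) follows a piecewise-linear
schedule inside the vector field, emulating on-line retuning of a running
chemostat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import CommunityParams, Trajectory, community_rhs, initial_state, simulate
from .lyapunov import (CHAOS_THRESHOLD_COMMUNITY, LyapunovConfig, classify_behaviour,
                       max_lyapunov)
from .model_space import EquationStructure
from .objectives import peak_amplitudes

__all__ = [
    "ScanResult",
    "RampSchedule",
    "evaluate_vector",
    "grid_scan",
    "sensitivity_scan",
    "bifurcation_scan",
    "ramp_simulation",
]


@dataclass
class ScanResult:
    """Per-cell exponents and labels over one or two swept axes."""

    axes: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    lambda1: np.ndarray            # NaN where no exponent was obtained
    labels: np.ndarray             # object array of classification strings
    extrema: list | None = None    # bifurcation scans: per-value peak levels
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if len(self.axes) == 1:
            rows = [{self.axes[0]: g, "lambda1": l, "label": lab}
                    for g, l, lab in zip(self.grids[0], self.lambda1, self.labels)]
        else:
            rows = []
            for i, gx in enumerate(self.grids[0]):
                for j, gy in enumerate(self.grids[1]):
                    rows.append({self.axes[0]: gx, self.axes[1]: gy,
                                 "lambda1": self.lambda1[i, j],
                                 "label": self.labels[i, j]})
        return pd.DataFrame(rows)


def _split_vector(structure: EquationStructure, vector: Mapping[str, float]
                  ) -> tuple[CommunityParams, np.ndarray]:
    params = CommunityParams.from_mapping(structure, vector)
    y0 = initial_state(structure, vector)
    return params, y0


def evaluate_vector(structure: EquationStructure, vector: Mapping[str, float],
                    t_end: float = 5000.0,
                    lyapunov_config: LyapunovConfig | None = None,
                    chaos_threshold: float = CHAOS_THRESHOLD_COMMUNITY,
                    ) -> tuple[float, str, Trajectory]:
    """Simulate one input vector and classify its dynamics.

    Returns ``(lambda1, label, trajectory)``; ``lambda1`` is NaN when the
    orbit goes extinct before an exponent can be estimated.
    """
    params, y0 = _split_vector(structure, vector)
    rhs = community_rhs(structure, params)
    n = structure.n_strains
    traj = simulate(rhs, y0, t_end=t_end, n_strains=n,
                    state_names=structure.state_names)
    cfg = lyapunov_config or LyapunovConfig(t_end=t_end, n_strains=n)
    if traj.termination.status != "completed":
        return np.nan, "extinct" if traj.termination.status == "extinction" else "failed", traj
    res = max_lyapunov(rhs, y0, cfg)
    label = classify_behaviour(res, traj, chaos_threshold, n)
    lam = res.lambda1 if res.lambda1 is not None else np.nan
    return lam, label, traj


def grid_scan(structure: EquationStructure, base_vector: Mapping[str, float],
              param_x: str, param_y: str,
              grid_x: Sequence[float], grid_y: Sequence[float],
              t_end: float = 5000.0,
              lyapunov_config: LyapunovConfig | None = None,
              chaos_threshold: float = CHAOS_THRESHOLD_COMMUNITY) -> ScanResult:
    """Two-parameter behaviour map around a reference input vector."""
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    lam = np.full((gx.size, gy.size), np.nan)
    labels = np.empty((gx.size, gy.size), dtype=object)
    for i, vx in enumerate(gx):
        for j, vy in enumerate(gy):
            vector = dict(base_vector)
            vector[param_x] = float(vx)
            vector[param_y] = float(vy)
            lam[i, j], labels[i, j], _ = evaluate_vector(
                structure, vector, t_end, lyapunov_config, chaos_threshold)
    return ScanResult(axes=(param_x, param_y), grids=(gx, gy),
                      lambda1=lam, labels=labels,
                      meta={"t_end": t_end})


def sensitivity_scan(structure: EquationStructure, base_vector: Mapping[str, float],
                     species: str, value_grid: Sequence[float],
                     t_end: float = 5000.0,
                     lyapunov_config: LyapunovConfig | None = None,
                     chaos_threshold: float = CHAOS_THRESHOLD_COMMUNITY) -> ScanResult:
    """1-D scan over a single initial condition (e.g. ``N_1``, ``B_1``)."""
    grid = np.asarray(value_grid, dtype=float)
    lam = np.full(grid.size, np.nan)
    labels = np.empty(grid.size, dtype=object)
    for i, v in enumerate(grid):
        vector = dict(base_vector)
        vector[species] = float(v)
        lam[i], labels[i], _ = evaluate_vector(
            structure, vector, t_end, lyapunov_config, chaos_threshold)
    return ScanResult(axes=(species,), grids=(grid,), lambda1=lam, labels=labels,
                      meta={"t_end": t_end, "kind": "initial_condition"})


def bifurcation_scan(structure: EquationStructure, base_vector: Mapping[str, float],
                     param: str, value_grid: Sequence[float],
                     species: str = "N_1",
                     t_end: float = 5000.0,
                     transient_fraction: float = 0.1,
                     dedup_tol: float = 1e-4,
                     lyapunov_config: LyapunovConfig | None = None,
                     chaos_threshold: float = CHAOS_THRESHOLD_COMMUNITY) -> ScanResult:
    """Attractor summary (post-transient peak levels) along one parameter.

    A fixed point contributes a single level, a limit cycle a few discrete
    levels, chaos a dense band — concatenated over the grid this draws the
    usual bifurcation diagram.
    """
    grid = np.asarray(value_grid, dtype=float)
    strain_idx = int(species.split("_")[1]) - 1
    lam = np.full(grid.size, np.nan)
    labels = np.empty(grid.size, dtype=object)
    extrema: list[np.ndarray] = []
    for i, v in enumerate(grid):
        vector = dict(base_vector)
        vector[param] = float(v)
        lam[i], labels[i], traj = evaluate_vector(
            structure, vector, t_end, lyapunov_config, chaos_threshold)
        if traj.termination.completed:
            x = traj.strain(strain_idx)
            x = x[int(transient_fraction * x.size):]
            g = np.diff(x)
            peaks = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0] + 1
            levels = x[peaks] if peaks.size else np.array([x[-1]])
            levels = np.unique(np.round(levels / dedup_tol) * dedup_tol)
        else:
            levels = np.array([])
        extrema.append(levels)
    return ScanResult(axes=(param,), grids=(grid,), lambda1=lam, labels=labels,
                      extrema=extrema, meta={"species": species, "t_end": t_end})


@dataclass(frozen=True)
class RampSchedule:
    """Piecewise-linear time course for one tunable parameter.

    ``param`` is ``"D"`` or a QS production rate like ``"kA_1"``; knots are
    (time, value) pairs with increasing times.  Before the first and after
    the last knot the value is held constant.
    """

    param: str
    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.knots]
        if len(times) < 1 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("knot times must be strictly increasing")

    def value(self, t: float) -> float:
        times = np.array([k[0] for k in self.knots])
        vals = np.array([k[1] for k in self.knots])
        return float(np.interp(t, times, vals))


def ramp_simulation(structure: EquationStructure, base_vector: Mapping[str, float],
                    schedule: RampSchedule,
                    t_end: float = 5000.0, dt_out: float = 1.0) -> Trajectory:
    """Integrate one trajectory while a parameter is retuned in real time.

    The parameter is a continuous function of time inside the vector field
    (one uninterrupted integration), mirroring on-line tuning of a running
    reactor rather than a sequence of restarts.
    """
    params, y0 = _split_vector(structure, base_vector)

    if schedule.param == "D":
        def override(t: float) -> dict:
            return {"D": schedule.value(t)}
    elif schedule.param.startswith("kA_"):
        y = int(schedule.param.split("_")[1])
        slot = structure.qs_systems.index(y)
        kA_base = params.kA.copy()

        def override(t: float) -> dict:
            kA = kA_base.copy()
            kA[slot] = schedule.value(t)
            return {"kA": kA}
    else:
        raise ValueError(f"unsupported ramp parameter {schedule.param!r}")

    rhs = community_rhs(structure, params, override=override)
    traj = simulate(rhs, y0, t_end=t_end, dt_out=dt_out,
                    n_strains=structure.n_strains,
                    state_names=structure.state_names)
    traj.meta.update({"ramp_param": schedule.param, "knots": schedule.knots})
    return traj


def stable_coexistence(traj: Trajectory, n_strains: int = 3,
                       window: float = 500.0,
                       amplitude_tol: float = 0.05,
                       extinction_threshold: float = 1e-5) -> bool:
    """Check that the final ``window`` hours show flat three-strain coexistence."""
    if not traj.termination.completed:
        return False
    dt = float(traj.times[1] - traj.times[0])
    k = max(2, int(window / dt))
    tail = traj.states[-k:, :n_strains]
    if np.any(tail.min(axis=0) < extinction_threshold):
        return False
    for x in range(n_strains):
        amps, _ = peak_amplitudes(tail[:, x])
        if any(a > amplitude_tol for a in amps):
            return False
        if tail[:, x].max() - tail[:, x].min() > 2 * amplitude_tol:
            return False
    return True
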