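"""ODE systems and integration for community dynamics.

Two model families are covered:

* the n-species competitive generalised Lotka-Volterra (gLV) system
  ``dN_i/dt = r_i N_i (1 - sum_j alpha_ij N_j)``, and
* the rescaled chemostat community model with Monod growth on a shared
  substrate, Hill-type bacteriocin killing, and QS-regulated bacteriocin
  expression.

Chemostat state layout is ``(N_1..N_n, S, B_z.., A_y..)`` with strain
densities in OD units, substrate in molar, and bacteriocin/QS
concentrations carried as rescaled state variables: the physical molar
concentration of bacteriocin z is ``B_z * C_B`` and of QS signal y is
``A_y * C_A``.  With the default scalings (``C_N = 1e9`` cells/OD,
``C_B = C_A = 1e-9``) all state variables are O(1)-O(100), which keeps the
stiff integrator happy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_space import EquationStructure, INDUCED, REPRESSED

try:  # optional acceleration; the numpy path is the reference implementation
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco

__all__ = [
    "GLVParams",
    "CommunityParams",
    "Termination",
    "Trajectory",
    "monod_growth",
    "kill_rate",
    "bacteriocin_expression",
    "community_rhs",
    "glv_rhs",
    "simulate",
    "initial_state",
    "EXTINCTION_THRESHOLD",
]

#: OD below which a strain is declared extinct and the simulation stops.
EXTINCTION_THRESHOLD = 1e-5

DEFAULT_T_END = 5000.0
DEFAULT_DT_OUT = 1.0
DEFAULT_RTOL = 1e-4
DEFAULT_ATOL = 1e-9


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLVParams:
    """Growth rates and interaction matrix of a competitive gLV system."""

    r: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "alpha", alpha)
        n = r.shape[0]
        if alpha.shape != (n, n):
            raise ValueError(f"alpha must be {n}x{n}, got {alpha.shape}")
        if not np.all(np.isfinite(alpha)) or not np.all(np.isfinite(r)):
            raise ValueError("non-finite gLV parameters")
        if np.any(r <= 0):
            raise ValueError("growth rates must be strictly positive")

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class CommunityParams:
    """Full parameterisation of a chemostat community model.

    Arrays are aligned with the slots of an :class:`EquationStructure`:
    ``mu_max`` per strain, ``kA`` per QS present, and ``KB_max``/``K_AB``/
    ``n_z`` per bacteriocin present.  Units: rates in 1/h, concentrations in
    M, densities in OD.
    """

    mu_max: np.ndarray          # h^-1, per strain
    kA: np.ndarray              # M h^-1 per cell, per QS slot
    KB_max: np.ndarray          # M h^-1 per cell, per bacteriocin slot
    K_AB: np.ndarray            # M, half-max regulation, per bacteriocin slot
    n_z: np.ndarray             # Hill coefficient of regulation, per bacteriocin slot
    D: float = 0.167            # h^-1 dilution rate
    K: float = 3.9e-5           # M Monod half saturation
    K_omega: float = 1.6e-7     # M half-max killing
    S0: float = 0.02            # M feed substrate
    gamma: float = 1e11         # cells / M substrate yield
    n_omega: float = 1.87       # Hill coefficient of killing
    omega_max: float = 0.79     # h^-1 max kill rate
    C_N: float = 1e9            # cells per OD unit
    C_B: float = 1e-9           # bacteriocin state rescaling
    C_A: float = 1e-9           # QS state rescaling

    def __post_init__(self) -> None:
        for name in ("mu_max", "kA", "KB_max", "K_AB", "n_z"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        scalars = [self.D, self.K, self.K_omega, self.S0, self.gamma,
                   self.n_omega, self.omega_max, self.C_N, self.C_B, self.C_A]
        if any(not np.isfinite(v) or v <= 0 for v in scalars):
            raise ValueError("all scalar parameters must be positive and finite")

    @classmethod
    def from_mapping(cls, structure: EquationStructure, values: Mapping[str, float]) -> "CommunityParams":
        """Build aligned parameter arrays from a flat name->value mapping.

        Expected names: ``mu_max_x`` per strain, ``kA_y`` per QS species in
        the model, ``KB_max_z``, ``K_A{y}B{z}`` and ``n_z`` per bacteriocin
        species ``z`` with regulator ``y``, plus the scalar fields.
        """
        mu_max = [values[f"mu_max_{x + 1}"] for x in range(structure.n_strains)]
        kA = [values[f"kA_{y}"] for y in structure.qs_systems]
        KB_max = [values[f"KB_max_{z}"] for z in structure.bacteriocins]
        K_AB = []
        n_hill = []
        for slot, z in enumerate(structure.bacteriocins):
            y = structure.qs_systems[structure.regulators[slot]]
            K_AB.append(values[f"K_A{y}B{z}"])
            n_hill.append(values[f"n_{z}"])
        scalars = {k: values[k] for k in ("D", "K", "K_omega", "S0", "gamma",
                                          "n_omega", "omega_max", "C_N", "C_B", "C_A")
                   if k in values}
        return cls(mu_max=np.array(mu_max), kA=np.array(kA), KB_max=np.array(KB_max),
                   K_AB=np.array(K_AB), n_z=np.array(n_hill), **scalars)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def monod_growth(mu_max: float, S: float, K: float) -> float:
    """Monod growth rate ``mu_max * S / (K + S)`` on limiting substrate."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    return mu_max * S / (K + S)


def kill_rate(omega_max: float, B_scaled: float, K_omega: float, n_omega: float,
              sensitive: bool = True, C_B: float = 1.0) -> float:
    """Hill-type killing rate; zero for insensitive strains.

    ``B_scaled`` is the rescaled bacteriocin state; ``B_scaled * C_B`` is the
    physical concentration compared against ``K_omega``.
    """
    if not sensitive:
        return 0.0
    B = max(float(B_scaled), 0.0) * C_B
    bn = B ** n_omega
    return omega_max * bn / (K_omega ** n_omega + bn)


def bacteriocin_expression(KB_max: float, A_scaled: float, K_AB: float, n_z: float,
                           mode: str = INDUCED, C_A: float = 1.0) -> float:
    """QS-regulated bacteriocin expression rate (per cell).

    Induced cassettes follow an activating Hill function of the QS signal,
    repressed cassettes the complementary repressing form.
    """
    A = max(float(A_scaled), 0.0) * C_A
    an = A ** n_z
    kn = K_AB ** n_z
    if mode == INDUCED:
        return KB_max * an / (kn + an)
    if mode == REPRESSED:
        return KB_max * kn / (kn + an)
    raise ValueError(f"unknown regulation mode {mode!r}")


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def glv_rhs(params: GLVParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vector field of the competitive gLV system."""
    r = params.r
    alpha = params.alpha

    def rhs(t: float, N: np.ndarray) -> np.ndarray:
        return r * N * (1.0 - alpha @ N)

    return rhs


@_njit(cache=True)
def _community_core(y, out, n, nb, na, mu_max, kA, KB_max, K_AB_n, n_z,
                    K, S0, CN_over_gamma, n_omega, omega_max, Kw_n,
                    C_B, C_A, CN_CB, CN_CA, D,
                    sens, prod_ind, prod_rep, qs_prod, reg_idx):
    """Derivative of one community state vector (compiled inner loop)."""
    # Strain densities enter linearly and are left unclamped so the field
    # stays smooth at the axes (correct linearisations at boundary fixed
    # points); only inputs to fractional powers are floored at zero to keep
    # tiny negative solver excursions from producing NaNs.
    S = y[n]
    growth_sum = 0.0
    for z in range(nb):
        b = y[n + 1 + z]
        if b < 0.0:
            b = 0.0
        Bn = (b * C_B) ** n_omega
        om = omega_max * Bn / (Kw_n + Bn)
        # reuse out slot as scratch for omega; overwritten below
        out[n + 1 + z] = om
    for x in range(n):
        N = y[x]
        mu = mu_max[x] * S / (K + S)
        kill = 0.0
        for z in range(nb):
            if sens[x, z] != 0.0:
                kill += out[n + 1 + z]
        out[x] = N * (mu - kill - D)
        growth_sum += mu * N
    # bacteriocin expression
    for z in range(nb):
        a = y[n + 1 + nb + reg_idx[z]]
        if a < 0.0:
            a = 0.0
        An = (a * C_A) ** n_z[z]
        hill_on = An / (K_AB_n[z] + An)
        prod = 0.0
        for x in range(n):
            N = y[x]
            if prod_ind[x, z] != 0.0:
                prod += N * hill_on
            elif prod_rep[x, z] != 0.0:
                prod += N * (1.0 - hill_on)
        out[n + 1 + z] = CN_CB * KB_max[z] * prod - D * y[n + 1 + z]
    out[n] = D * (S0 - S) - CN_over_gamma * growth_sum
    for q in range(na):
        prod = 0.0
        for x in range(n):
            if qs_prod[x, q] != 0.0:
                prod += y[x]
        out[n + 1 + nb + q] = CN_CA * kA[q] * prod - D * y[n + 1 + nb + q]
    return out


def community_rhs(structure: EquationStructure, params: CommunityParams,
                  override: Callable[[float], Mapping[str, float]] | None = None,
                  ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vector field of a chemostat community model.

    ``override``, if given, maps time to a dict of scalar parameter updates
    (currently ``D`` and per-slot ``kA``); used for real-time parameter ramps.
    """
    n = structure.n_strains
    nb = len(structure.bacteriocins)
    na = len(structure.qs_systems)
    if params.mu_max.shape[0] != n or params.kA.shape[0] != na or params.KB_max.shape[0] != nb:
        raise ValueError("parameter arrays do not match the equation structure")

    sens = np.zeros((n, nb))
    for x, slots in enumerate(structure.sensitivity):
        for k in slots:
            sens[x, k] = 1.0
    prod_ind = np.zeros((n, nb))
    prod_rep = np.zeros((n, nb))
    for k, producers in enumerate(structure.producers):
        for x, mode in producers:
            (prod_ind if mode == INDUCED else prod_rep)[x, k] = 1.0
    qs_prod = np.zeros((n, na))
    for k, producers in enumerate(structure.qs_producers):
        for x in producers:
            qs_prod[x, k] = 1.0
    reg_idx = np.asarray(structure.regulators, dtype=int)

    mu_max, kA0, KB_max = params.mu_max, params.kA, params.KB_max
    K_AB_n = params.K_AB ** params.n_z
    n_z = params.n_z
    K, K_omega, S0, gamma = params.K, params.K_omega, params.S0, params.gamma
    n_omega, omega_max = params.n_omega, params.omega_max
    C_N, C_B, C_A = params.C_N, params.C_B, params.C_A
    Kw_n = K_omega ** n_omega
    D0 = params.D

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        D, kA = D0, kA0
        if override is not None:
            upd = override(t)
            D = upd.get("D", D0)
            if "kA" in upd:
                kA = upd["kA"]
        # strains enter linearly (unclamped; keeps the field smooth at the
        # axes); only fractional-power inputs are floored at zero
        N = y[:n]
        S = y[n]
        b = np.maximum(y[n + 1:n + 1 + nb], 0.0)
        a = np.maximum(y[n + 1 + nb:], 0.0)
        mu = mu_max * S / (K + S)
        out = np.empty_like(y)
        if nb:
            Bn = (b * C_B) ** n_omega
            omega = omega_max * Bn / (Kw_n + Bn)
            kill = sens @ omega
            An = (a * C_A)[reg_idx] ** n_z
            hill_on = An / (K_AB_n + An)
            expr = KB_max * ((N @ prod_ind) * hill_on + (N @ prod_rep) * (1.0 - hill_on))
            out[n + 1:n + 1 + nb] = (C_N / C_B) * expr - D * y[n + 1:n + 1 + nb]
        else:
            kill = 0.0
        out[:n] = N * (mu - kill - D)
        out[n] = D * (S0 - S) - (C_N / gamma) * (mu @ N)
        if na:
            out[n + 1 + nb:] = (C_N / C_A) * kA * (N @ qs_prod) - D * y[n + 1 + nb:]
        return out

    if _HAVE_NUMBA and override is None:
        m_states = n + 1 + nb + na
        args = (n, nb, na, mu_max, kA0, KB_max, K_AB_n, n_z, K, S0,
                C_N / gamma, n_omega, omega_max, Kw_n, C_B, C_A,
                C_N / C_B, C_N / C_A, D0, sens, prod_ind, prod_rep, qs_prod,
                reg_idx.astype(np.int64))

        def rhs_fast(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty(m_states)
            _community_core(np.asarray(y, dtype=float), out, *args)
            return out

        def pair_rhs(y: np.ndarray, t: float) -> np.ndarray:
            out = np.empty(2 * m_states)
            yy = np.asarray(y, dtype=float)
            _community_core(yy[:m_states], out[:m_states], *args)
            _community_core(yy[m_states:], out[m_states:], *args)
            return out

        rhs_fast.pair_rhs = pair_rhs  # fast combined field for dual-orbit stepping
        rhs_fast.reference = rhs      # pure-numpy implementation of the same field
        return rhs_fast

    return rhs


def initial_state(structure: EquationStructure, values: Mapping[str, float]) -> np.ndarray:
    """Assemble a state vector from named initial conditions.

    Expected names: ``N_x`` per strain, ``S``, ``B_z`` per bacteriocin in
    the model, ``A_y`` per QS in the model.
    """
    parts = [values[f"N_{x + 1}"] for x in range(structure.n_strains)]
    parts.append(values["S"])
    parts += [values[f"B_{z}"] for z in structure.bacteriocins]
    parts += [values[f"A_{y}"] for y in structure.qs_systems]
    return np.array(parts, dtype=float)


# ---------------------------------------------------------------------------
# Trajectories and integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Termination:
    status: str                 # "completed" | "extinction" | "failed"
    time: float | None = None   # extinction/failure time
    strain: int | None = None   # 0-based index of the extinct strain

    @property
    def completed(self) -> bool:
        return self.status == "completed"


@dataclass
class Trajectory:
    """Uniformly sampled multi-species time series with termination metadata."""

    times: np.ndarray
    states: np.ndarray          # shape (n_times, n_states)
    termination: Termination
    state_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.states.shape[1]

    def strain(self, x: int) -> np.ndarray:
        return self.states[:, x]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def strain_signals(self, n_strains: int) -> np.ndarray:
        return self.states[:, :n_strains]

    def to_frame(self) -> pd.DataFrame:
        names = self.state_names or tuple(f"y{i}" for i in range(self.n_states))
        df = pd.DataFrame(self.states, columns=list(names))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = dict(self.meta)
        meta["termination"] = {"status": self.termination.status,
                               "time": self.termination.time,
                               "strain": self.termination.strain}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))


def simulate(rhs: Callable[[float, np.ndarray], np.ndarray],
             state0: Sequence[float],
             t_end: float = DEFAULT_T_END,
             dt_out: float = DEFAULT_DT_OUT,
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL,
             extinction_threshold: float | None = EXTINCTION_THRESHOLD,
             n_strains: int | None = None,
             t_start: float = 0.0,
             state_names: Sequence[str] = (),
             method: str = "LSODA") -> Trajectory:
    """Integrate ``rhs`` on a uniform output grid with early extinction stop.

    ``n_strains`` marks the leading state components monitored against the
    extinction threshold; pass ``extinction_threshold=None`` (e.g. for gLV
    validation runs on dimensionless abundances) to disable early stopping.
    Integrator failures are surfaced as a ``failed`` termination rather than
    an exception so that batch drivers can treat them as maximal distance.
    """
    y0 = np.asarray(state0, dtype=float)
    if np.any(~np.isfinite(y0)):
        raise ValueError("non-finite initial state")
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    t_eval = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    events = []
    if extinction_threshold is not None:
        nx = n_strains if n_strains is not None else y0.shape[0]

        def extinct(t, y, nx=nx, thr=extinction_threshold):
            return float(np.min(y[:nx]) - thr)

        extinct.terminal = True
        extinct.direction = -1.0
        events.append(extinct)

    try:
        sol = solve_ivp(rhs, (t_start, t_end), y0, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol, events=events or None, dense_output=False)
    except (ValueError, FloatingPointError):
        return Trajectory(times=np.array([t_start]), states=y0[None, :],
                          termination=Termination("failed", time=t_start),
                          state_names=tuple(state_names))
    if sol.status == 1 and events:  # terminal event: extinction
        t_ev = float(sol.t_events[0][0])
        y_ev = sol.y_events[0][0]
        strain = int(np.argmin(y_ev[:nx]))
        times = np.append(sol.t, t_ev) if (sol.t.size == 0 or sol.t[-1] < t_ev) else sol.t
        states = np.vstack([sol.y.T, y_ev[None, :]]) if times.size > sol.t.size else sol.y.T
        term = Termination("extinction", time=t_ev, strain=strain)
        return Trajectory(times=times, states=states, termination=term,
                          state_names=tuple(state_names))
    if sol.status != 0:
        return Trajectory(times=sol.t, states=sol.y.T,
                          termination=Termination("failed", time=float(sol.t[-1]) if sol.t.size else t_start),
                          state_names=tuple(state_names))
    return Trajectory(times=sol.t, states=sol.y.T, termination=Termination("completed"),
                      state_names=tuple(state_names))
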