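"""Steady states and stability of the four-part chaotic topology.

For the community in which one QS signal (produced by strain 1) induces two
bacteriocins — B1 made by strains 1 and 2 and killing strain 1, B2 made and
felt by strain 3 — the fixed points with state order
``(N1, N2, N3, S, B1, B2, A1)`` are:

* ``P0``   washout: all strains extinct, substrate at the feed level;
* ``P2``, ``P3``  single-survivor states with closed-form coordinates;
* ``P1``   survivor-1 state, defined implicitly through a scalar balance
  between Monod growth and self-killing (unique root in substrate when the
  dilution rate is below the strain's washout limit);
* ``P123`` three-strain coexistence, found by multivariate root finding.

Eigenvalues of the linearisation are available in closed form for P0, P2
and P3; all states are also checked against a central-finite-difference
Jacobian of the full right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .dynamics import CommunityParams, community_rhs, simulate
from .model_space import build_equation_structure, reference_topology

__all__ = [
    "SteadyState",
    "StabilityReport",
    "trivial_state",
    "single_strain_states",
    "coexistence_conditions",
    "find_coexistence_state",
    "numerical_jacobian",
]

_STATE_NAMES = ("N1", "N2", "N3", "S", "B1", "B2", "A1")
RESIDUAL_TOL = 1e-8
STABILITY_TOL = 1e-10


@dataclass(frozen=True)
class SteadyState:
    label: str
    coordinates: np.ndarray | None
    exists: bool
    residual: float = np.nan
    note: str = ""

    def as_dict(self) -> dict:
        coords = None if self.coordinates is None else dict(zip(_STATE_NAMES, self.coordinates))
        return {"label": self.label, "exists": self.exists,
                "coordinates": coords, "residual": self.residual, "note": self.note}


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray | None
    stable: bool | None
    analytic_conditions: dict

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real)) if self.eigenvalues is not None else np.nan


def _rhs(params: CommunityParams):
    return community_rhs(build_equation_structure(reference_topology()), params)


def _residual(params: CommunityParams, y: np.ndarray) -> float:
    return float(np.linalg.norm(_rhs(params)(0.0, y)))


def numerical_jacobian(f, y: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Richardson-extrapolated central-difference Jacobian of ``f(y)``.

    Combining central differences at steps h and h/2 cancels the leading
    truncation term, which matters for sharply curved directions (e.g. the
    substrate axis, whose Monod curvature scale is the half-saturation
    constant, far below 1).
    """
    y = np.asarray(y, dtype=float)
    m = y.size

    def central(h_vec):
        J = np.empty((m, m))
        for j in range(m):
            yp, ym = y.copy(), y.copy()
            yp[j] += h_vec[j]
            ym[j] -= h_vec[j]
            J[:, j] = (f(yp) - f(ym)) / (2.0 * h_vec[j])
        return J

    h = rel_step * np.maximum(np.abs(y), 1.0)
    J_h = central(h)
    J_h2 = central(h / 2.0)
    return (4.0 * J_h2 - J_h) / 3.0


def _jacobian_eigs(params: CommunityParams, y: np.ndarray) -> np.ndarray:
    f = _rhs(params)
    J = numerical_jacobian(lambda yy: f(0.0, yy), y)
    return np.linalg.eigvals(J)


def _monod(params: CommunityParams, x: int, S: float) -> float:
    return params.mu_max[x] * S / (params.K + S)


# ---------------------------------------------------------------------------
# P0: washout
# ---------------------------------------------------------------------------

def trivial_state(params: CommunityParams) -> tuple[SteadyState, StabilityReport]:
    """The always-existing washout state and its closed-form eigenvalues.

    Linearisation eigenvalues: ``-D`` (substrate and each bacteriocin/QS
    direction) and ``mu_x(S0) - D`` per strain; stable exactly when the
    dilution rate exceeds every strain's growth rate at the feed substrate.
    """
    p = params
    y = np.array([0.0, 0.0, 0.0, p.S0, 0.0, 0.0, 0.0])
    growth = np.array([_monod(p, x, p.S0) for x in range(3)])
    eigs = np.concatenate(([-p.D], growth - p.D, [-p.D, -p.D, -p.D]))
    cond_value = p.S0 / (p.S0 + p.K) * float(np.max(p.mu_max))
    conditions = {
        "D > S0/(S0+K) * max(mu_max)": {
            "lhs": p.D, "rhs": cond_value, "satisfied": p.D > cond_value},
    }
    state = SteadyState("P0", y, exists=True, residual=_residual(p, y))
    report = StabilityReport(eigenvalues=eigs.astype(complex),
                             stable=bool(np.max(eigs) < -STABILITY_TOL),
                             analytic_conditions=conditions)
    return state, report


# ---------------------------------------------------------------------------
# P2 / P3: single-survivor closed forms
# ---------------------------------------------------------------------------

def _survivor_no_killing(params: CommunityParams, x: int, label: str
                         ) -> tuple[SteadyState, StabilityReport]:
    """Closed-form single-survivor state for a strain not killing itself.

    The surviving strain grows at exactly the dilution rate, pinning the
    substrate at ``S = D K / (mu_max - D)``; its density follows from the
    substrate balance.  Exists iff ``D < mu_max S0/(S0+K)``.
    """
    p = params
    mu = float(p.mu_max[x])
    exists = p.D < mu * p.S0 / (p.S0 + p.K)
    others = [i for i in range(3) if i != x]
    conditions = {
        "D < mu_max*S0/(S0+K)": {"lhs": p.D, "rhs": mu * p.S0 / (p.S0 + p.K),
                                 "satisfied": exists},
        "mu_max largest": {"lhs": mu, "rhs": float(np.max(p.mu_max[others])),
                           "satisfied": mu > float(np.max(p.mu_max[others]))},
    }
    if not exists or mu <= p.D:
        return (SteadyState(label, None, exists=False),
                StabilityReport(None, None, conditions))
    S = p.D * p.K / (mu - p.D)
    N = p.gamma * (p.S0 - S) / p.C_N
    y = np.zeros(7)
    y[x] = N
    y[3] = S
    eigs = [-p.D]
    for i in others:
        eigs.append(-p.D * (1.0 - float(p.mu_max[i]) / mu))
    eigs.append(-(mu - p.D) * (mu * p.S0 - p.D * (p.S0 + p.K)) / (p.K * mu))
    eigs += [-p.D, -p.D, -p.D]   # bacteriocin and QS directions
    eigs = np.array(eigs, dtype=complex)
    state = SteadyState(label, y, exists=True, residual=_residual(p, y))
    report = StabilityReport(eigenvalues=eigs,
                             stable=bool(np.max(eigs.real) < -STABILITY_TOL),
                             analytic_conditions=conditions)
    return state, report


def _p1_profile(params: CommunityParams, S: float) -> tuple[float, float, float]:
    """Scaled (N1, B1, A1) of the survivor-1 branch as functions of S."""
    p = params
    mu1 = _monod(p, 0, S)
    N1_cells = p.gamma * p.D * (p.S0 - S) / mu1
    a1 = p.kA[0] * N1_cells / (p.C_A * p.D)
    A_phys = a1 * p.C_A
    n1 = float(p.n_z[0])
    kB1 = float(p.KB_max[0]) * A_phys ** n1 / (float(p.K_AB[0]) ** n1 + A_phys ** n1)
    b1 = kB1 * N1_cells / (p.C_B * p.D)
    return N1_cells / p.C_N, b1, a1


def _p1_balance(params: CommunityParams, S: float) -> float:
    """Growth-minus-killing balance whose root defines P1."""
    p = params
    _, b1, _ = _p1_profile(p, S)
    B_phys = b1 * p.C_B
    kill = p.omega_max * B_phys ** p.n_omega / (p.K_omega ** p.n_omega + B_phys ** p.n_omega)
    return (_monod(p, 0, S) - p.D) - kill


def _survivor_one(params: CommunityParams) -> tuple[SteadyState, StabilityReport]:
    p = params
    lemma = p.D < float(p.mu_max[0]) * p.S0 / (p.K + p.S0)
    conditions = {
        "D < mu_max1*S0/(K+S0)": {
            "lhs": p.D, "rhs": float(p.mu_max[0]) * p.S0 / (p.K + p.S0),
            "satisfied": lemma},
    }
    if not lemma:
        return (SteadyState("P1", None, exists=False),
                StabilityReport(None, None, conditions))
    eps = 1e-12 * p.S0
    try:
        S = brentq(lambda s: _p1_balance(p, s), eps, p.S0 - eps,
                   xtol=1e-18, rtol=1e-15, maxiter=500)
    except ValueError as exc:  # bracketing failure despite the existence lemma
        raise RuntimeError("P1 root-finding failed although the existence "
                           "condition holds") from exc
    N1, b1, a1 = _p1_profile(p, S)
    y = np.array([N1, 0.0, 0.0, S, b1, 0.0, a1])
    eigs = _jacobian_eigs(p, y)
    state = SteadyState("P1", y, exists=True, residual=_residual(p, y))
    report = StabilityReport(eigenvalues=eigs,
                             stable=bool(np.max(eigs.real) < -STABILITY_TOL),
                             analytic_conditions=conditions)
    return state, report


def single_strain_states(params: CommunityParams) -> dict[str, tuple[SteadyState, StabilityReport]]:
    """The three single-survivor states P1 (implicit), P2 and P3 (closed form)."""
    return {
        "P1": _survivor_one(params),
        "P2": _survivor_no_killing(params, 1, "P2"),
        "P3": _survivor_no_killing(params, 2, "P3"),
    }


# ---------------------------------------------------------------------------
# P123: three-strain coexistence
# ---------------------------------------------------------------------------

def coexistence_conditions(params: CommunityParams) -> dict:
    """Necessary conditions for three-strain coexistence.

    Strain 2 (unkilled, growth-limited only by resource competition) must
    grow at exactly the dilution rate, which pins the substrate; its maximal
    growth rate must sit between a washout-driven lower bound and the other
    strains' maximal rates.
    """
    p = params
    mu1, mu2, mu3 = (float(v) for v in p.mu_max)
    lower = max(p.D * (p.K + p.S0) / p.S0,
                mu1 * p.D / (p.D + p.omega_max),
                mu3 * p.D / (p.D + p.omega_max))
    upper = min(mu1, mu3)
    d_bounds = [mu2 * p.S0 / (p.K + p.S0)]
    if mu1 > mu2:
        d_bounds.append(p.omega_max * mu2 / (mu1 - mu2))
    if mu3 > mu2:
        d_bounds.append(p.omega_max * mu2 / (mu3 - mu2))
    d_upper = min(d_bounds)
    record = {
        "substrate": {"S": p.D * p.K / (mu2 - p.D) if mu2 > p.D else np.inf},
        "lower < mu_max2": {"lhs": lower, "rhs": mu2, "satisfied": lower < mu2},
        "mu_max2 < min(mu_max1, mu_max3)": {"lhs": mu2, "rhs": upper,
                                            "satisfied": mu2 < upper},
        "D < bound": {"lhs": p.D, "rhs": d_upper, "satisfied": p.D < d_upper},
    }
    record["satisfied"] = all(v["satisfied"] for k, v in record.items()
                              if isinstance(v, dict) and "satisfied" in v)
    return record


def _default_guess(params: CommunityParams) -> np.ndarray:
    """Post-transient average of a trajectory from a generic inoculum."""
    structure = build_equation_structure(reference_topology())
    rhs = community_rhs(structure, params)
    y0 = np.array([0.2, 0.2, 0.2, params.S0, 1e-30, 1e-30, 1e-30])
    traj = simulate(rhs, y0, t_end=2000.0, n_strains=3)
    if traj.termination.completed:
        tail = traj.states[traj.states.shape[0] // 2:]
        return np.maximum(tail.mean(axis=0), 1e-12)
    return np.array([0.2, 0.2, 0.2, params.S0 / 10, 10.0, 10.0, 10.0])


def find_coexistence_state(params: CommunityParams,
                           initial_guess: np.ndarray | None = None,
                           n_restarts: int = 20,
                           seed: int = 0) -> tuple[SteadyState, StabilityReport]:
    """Locate the interior fixed point with all three strains positive.

    Uses damped Newton (hybr) from the supplied guess or from the state-space
    average of a post-transient trajectory, with random restarts on failure.
    Stability is judged from the eigenvalues of the finite-difference
    Jacobian at the root.
    """
    p = params
    conditions = coexistence_conditions(p)
    if not conditions["satisfied"]:
        return (SteadyState("P123", None, exists=False,
                            note="necessary conditions violated"),
                StabilityReport(None, None, conditions))
    f = _rhs(p)

    def F(y):
        return f(0.0, y)

    guess = np.asarray(initial_guess, dtype=float) if initial_guess is not None \
        else _default_guess(p)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        g = guess if attempt == 0 else guess * rng.uniform(0.7, 1.3, guess.size)
        sol = root(F, g, method="hybr", tol=1e-14)
        y = sol.x
        if not sol.success:
            continue
        res = float(np.linalg.norm(F(y)))
        if np.all(y[:3] > 0) and np.all(y >= -1e-12) and res < RESIDUAL_TOL:
            best = (y, res)
            break
    if best is None:
        return (SteadyState("P123", None, exists=False,
                            note="root finder did not converge"),
                StabilityReport(None, None, conditions))
    y, res = best
    eigs = _jacobian_eigs(p, y)
    state = SteadyState("P123", y, exists=True, residual=res)
    report = StabilityReport(eigenvalues=eigs,
                             stable=bool(np.max(eigs.real) < -STABILITY_TOL),
                             analytic_conditions=conditions)
    return state, report
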