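"""Approximate Bayesian Computation with Sequential Monte Carlo (ABC SMC).

Joint model selection and parameter inference for a target *behaviour*: a
particle is a (model, parameter vector) pair; its distance to the objective
is computed by simulating the model and summarising the trajectory
(oscillation distances or the chaos distance).  Populations of accepted
particles are evolved through a shrinking threshold schedule: the next
threshold is the per-component alpha-quantile of the current population's
distances, floored at the final threshold eps_F.  Weights follow the
standard importance-sampling ratio (prior density over kernel-smoothed
previous population), with generation-0 weights equal to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_space import EquationStructure
from .objectives import DistanceVector

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "Particle",
    "Population",
    "SMCConfig",
    "SMCResult",
    "sample_prior",
    "perturb",
    "compute_weight",
    "update_epsilon",
    "run_smc",
    "community_prior",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamPrior:
    """Uniform prior for one parameter, optionally on a log10 scale.

    Constants are expressed as ``lo == hi``.
    """

    name: str
    lo: float
    hi: float
    scale: str = "linear"       # "linear" | "log10"

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"{self.name}: min > max")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log10" and self.lo <= 0:
            raise ValueError(f"{self.name}: log10 scale requires positive bounds")

    @property
    def constant(self) -> bool:
        return self.lo == self.hi

    def to_u(self, value: float) -> float:
        """Map to the sampling scale."""
        return math.log10(value) if self.scale == "log10" else value

    def from_u(self, u: float) -> float:
        return 10.0 ** u if self.scale == "log10" else u

    @property
    def u_range(self) -> tuple[float, float]:
        return self.to_u(self.lo), self.to_u(self.hi)

    def sample(self, rng: np.random.Generator) -> float:
        lo_u, hi_u = self.u_range
        return self.from_u(rng.uniform(lo_u, hi_u)) if lo_u < hi_u else self.lo

    def in_support(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class PriorSpec:
    """Ordered collection of parameter priors for one model."""

    params: tuple[ParamPrior, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def n(self) -> int:
        return len(self.params)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample(rng) for p in self.params])

    def in_support(self, theta: np.ndarray) -> bool:
        return all(p.in_support(v) for p, v in zip(self.params, theta))

    def as_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, theta))

    def log_density(self, theta: np.ndarray) -> float:
        """Log prior density on the sampling scale (-inf outside support)."""
        total = 0.0
        for p, v in zip(self.params, theta):
            if not p.in_support(v):
                return -np.inf
            if not p.constant:
                lo_u, hi_u = p.u_range
                total -= math.log(hi_u - lo_u)
        return total


# ---------------------------------------------------------------------------
# Particles and populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Particle:
    model_id: int
    theta: np.ndarray
    distances: DistanceVector | None = None
    weight: float = 1.0


@dataclass
class Population:
    particles: list[Particle]
    eps: tuple[float, ...]
    t: int
    n_simulations: int = 0      # draws spent filling this population

    def normalise(self) -> None:
        total = sum(p.weight for p in self.particles)
        if total <= 0:
            raise ValueError("non-positive total weight")
        self.particles = [replace(p, weight=p.weight / total) for p in self.particles]

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    @property
    def distance_matrix(self) -> np.ndarray:
        return np.array([p.distances.values for p in self.particles])

    def model_masses(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for p in self.particles:
            out[p.model_id] = out.get(p.model_id, 0.0) + p.weight
        return out


@dataclass(frozen=True)
class SMCConfig:
    pop_size: int = 10
    alpha: float = 0.5              # threshold quantile
    kernel_factor: float = 0.1      # kernel half-width as fraction of prior range
    p_model: float = 0.1            # probability of proposing a model switch
    max_generations: int = 20
    max_draws_per_generation: int = 20000
    t_end: float = 5000.0           # simulation horizon passed to objectives


@dataclass
class SMCResult:
    populations: list[Population]
    status: str                      # "converged" | "max_generations" | "stalled"
    eps_final: tuple[float, ...]
    model_prior: tuple[int, ...]
    n_repeats: int = 1

    @property
    def final_population(self) -> Population:
        return self.populations[-1]

    def model_posterior(self) -> pd.DataFrame:
        """Weighted posterior mass per model (mean and std across repeats)."""
        masses = []
        for pop in self._final_populations:
            m = pop.model_masses()
            masses.append([m.get(mid, 0.0) for mid in self.model_prior])
        arr = np.array(masses)
        return pd.DataFrame({
            "model_id": self.model_prior,
            "posterior_mean": arr.mean(axis=0),
            "posterior_std": arr.std(axis=0),
        })

    _final_populations: list[Population] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def sample_prior(model_ids: Sequence[int],
                 prior_for_model: Callable[[int], PriorSpec],
                 rng: np.random.Generator) -> Particle:
    """Draw an unweighted particle from the joint (model, theta) prior."""
    mid = int(model_ids[int(rng.integers(len(model_ids)))])
    prior = prior_for_model(mid)
    return Particle(model_id=mid, theta=prior.sample(rng))


def _kernel_widths(prior: PriorSpec, kernel_factor: float) -> np.ndarray:
    widths = np.empty(prior.n)
    for i, p in enumerate(prior.params):
        lo_u, hi_u = p.u_range
        widths[i] = kernel_factor * (hi_u - lo_u)
    return widths


def perturb(particle: Particle,
            model_ids: Sequence[int],
            prior_for_model: Callable[[int], PriorSpec],
            rng: np.random.Generator,
            kernel_factor: float = 0.1,
            p_model: float = 0.1,
            max_tries: int = 1000) -> Particle:
    """Perturb a particle within prior support.

    The parameter kernel is a componentwise uniform kernel on the sampling
    scale with half-width ``kernel_factor`` times the prior range;
    out-of-support proposals are redrawn.  With probability ``p_model`` the
    model is switched to a uniformly random *other* model and the parameters
    are drawn fresh from that model's prior.
    """
    if len(model_ids) > 1 and p_model > 0 and rng.uniform() < p_model:
        others = [m for m in model_ids if m != particle.model_id]
        mid = int(others[int(rng.integers(len(others)))])
        prior = prior_for_model(mid)
        return Particle(model_id=mid, theta=prior.sample(rng))
    prior = prior_for_model(particle.model_id)
    widths = _kernel_widths(prior, kernel_factor)
    u0 = np.array([p.to_u(v) for p, v in zip(prior.params, particle.theta)])
    for _ in range(max_tries):
        u = u0 + rng.uniform(-widths, widths)
        theta = np.array([p.from_u(v) for p, v in zip(prior.params, u)])
        if prior.in_support(theta):
            return Particle(model_id=particle.model_id, theta=theta)
    raise RuntimeError("perturbation failed to find an in-support proposal")


def _kernel_log_density(prior: PriorSpec, widths: np.ndarray,
                        theta_from: np.ndarray, theta_to: np.ndarray) -> float:
    """Log density of the uniform componentwise kernel K(theta_to | theta_from)."""
    total = 0.0
    for p, w, a, b in zip(prior.params, widths, theta_from, theta_to):
        if p.constant:
            continue
        if w <= 0:
            if a != b:
                return -np.inf
            continue
        if abs(p.to_u(b) - p.to_u(a)) > w:
            return -np.inf
        total -= math.log(2.0 * w)
    return total


def compute_weight(particle: Particle,
                   prev_population: Population,
                   prior_for_model: Callable[[int], PriorSpec],
                   kernel_factor: float = 0.1,
                   generation: int = 0) -> float:
    """Importance weight of an accepted particle.

    Generation 0 weights are 1.  Later generations use
    ``pi(theta) / sum_j w_j K(theta | theta_j)`` where the sum runs over the
    previous population's particles of the same model (parameter spaces
    differ between models).  A zero denominator indicates a kernel support
    violation and raises ``ZeroDivisionError``.
    """
    if generation == 0:
        return 1.0
    prior = prior_for_model(particle.model_id)
    widths = _kernel_widths(prior, kernel_factor)
    log_pi = prior.log_density(particle.theta)
    if not np.isfinite(log_pi):
        return 0.0
    denom = 0.0
    for prev in prev_population.particles:
        if prev.model_id != particle.model_id:
            continue
        lk = _kernel_log_density(prior, widths, prev.theta, particle.theta)
        if np.isfinite(lk):
            denom += prev.weight * math.exp(lk)
    if denom == 0.0:
        raise ZeroDivisionError("no previous same-model particle covers the proposal")
    return math.exp(log_pi) / denom


def update_epsilon(distances: np.ndarray, alpha: float,
                   eps_final: Sequence[float],
                   eps_current: Sequence[float] | None = None) -> tuple[tuple[float, ...], bool]:
    """Next threshold: per-component lower alpha-quantile, floored at eps_F.

    Returns ``(eps_next, is_final)`` where ``is_final`` flags that the floor
    was reached, marking the next population as the final one.
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if d.size == 0:
        raise ValueError("empty distance collection")
    q = np.quantile(d, alpha, axis=0, method="lower")
    eps_f = np.asarray(eps_final, dtype=float)
    eps_next = np.maximum(q, eps_f)
    if eps_current is not None:
        eps_next = np.minimum(eps_next, np.asarray(eps_current, dtype=float))
    return tuple(eps_next), bool(np.all(eps_next <= eps_f))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _sample_from_population(pop: Population, rng: np.random.Generator) -> Particle:
    w = pop.weights
    idx = int(rng.choice(len(pop.particles), p=w / w.sum()))
    return pop.particles[idx]


def _run_single_chain(model_ids, prior_for_model, distance_fn, eps_final,
                      config: SMCConfig, rng) -> tuple[list[Population], str]:
    eps_f = tuple(float(e) for e in eps_final)
    eps_t: tuple[float, ...] = (np.inf,) * len(eps_f)
    populations: list[Population] = []
    is_final = False
    for t in range(config.max_generations):
        particles: list[Particle] = []
        draws = 0
        while len(particles) < config.pop_size:
            if draws >= config.max_draws_per_generation:
                return populations, "stalled"
            draws += 1
            if t == 0:
                cand = sample_prior(model_ids, prior_for_model, rng)
            else:
                cand = perturb(_sample_from_population(populations[-1], rng),
                               model_ids, prior_for_model, rng,
                               config.kernel_factor, config.p_model)
            d = distance_fn(cand.model_id,
                            prior_for_model(cand.model_id).as_dict(cand.theta),
                            rng)
            if not d.accepted(eps_t):
                continue
            try:
                w = compute_weight(replace(cand, distances=d), populations[-1] if t else None,
                                   prior_for_model, config.kernel_factor, generation=t)
            except ZeroDivisionError:
                continue
            if w <= 0:
                continue
            particles.append(replace(cand, distances=d, weight=w))
        pop = Population(particles=particles, eps=eps_t, t=t, n_simulations=draws)
        pop.normalise()
        populations.append(pop)
        if is_final:
            return populations, "converged"
        eps_t, is_final = update_epsilon(pop.distance_matrix, config.alpha, eps_f, eps_t)
    return populations, "max_generations"


def run_smc(model_ids: Sequence[int],
            prior_for_model: Callable[[int], PriorSpec],
            distance_fn: Callable[[int, Mapping[str, float], np.random.Generator], DistanceVector],
            eps_final: Sequence[float],
            config: SMCConfig | None = None,
            rng: np.random.Generator | int | None = None,
            repeats: int = 1) -> SMCResult:
    """Run ABC SMC, optionally as several independent repeats.

    The model prior is uniform over ``model_ids``.  ``distance_fn`` maps a
    (model id, named parameters, rng) triple to a :class:`DistanceVector`;
    sentinel/rejected vectors are never accepted regardless of threshold.
    With ``repeats > 1`` the final populations of all repeats are pooled
    (the combined-population design) and the posterior standard deviation
    is taken across repeats.
    """
    config = config or SMCConfig()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    all_pops: list[Population] = []
    finals: list[Population] = []
    statuses = []
    for rep in range(repeats):
        sub_rng = np.random.default_rng(rng.integers(2 ** 31)) if repeats > 1 else rng
        pops, status = _run_single_chain(model_ids, prior_for_model, distance_fn,
                                         eps_final, config, sub_rng)
        statuses.append(status)
        if pops:
            all_pops.extend(pops)
            finals.append(pops[-1])
    if not finals:
        status = "stalled"
    elif all(s == "converged" for s in statuses):
        status = "converged"
    elif any(s == "stalled" for s in statuses):
        status = "stalled"
    else:
        status = "max_generations"
    result = SMCResult(populations=all_pops, status=status,
                       eps_final=tuple(float(e) for e in eps_final),
                       model_prior=tuple(int(m) for m in model_ids),
                       n_repeats=repeats)
    result._final_populations = finals
    return result


# ---------------------------------------------------------------------------
# Community-model glue
# ---------------------------------------------------------------------------

#: prior ranges spanning >= 3 decades default to log10-uniform sampling
LOG_SCALE_TEMPLATE_ROWS = ("kA", "KB_max", "K_AB", "K_omega")


def community_prior(structure: EquationStructure, prior_config: Mapping,
                    regulator_species: Mapping[int, int] | None = None) -> PriorSpec:
    """Expand the prior-bounds template into a per-model :class:`PriorSpec`.

    Template rows (``mu_max``, ``kA``, ``KB_max``, ``K_AB``, ``n_z``) are
    instantiated once per strain / QS / bacteriocin present in the model;
    scalar rows and the initial-state block are copied through.  The
    resulting names match :meth:`CommunityParams.from_mapping` and
    :func:`initial_state`.
    """
    pt = prior_config["parameters"]
    it = prior_config["initial_state"]

    def row(src, name):
        r = src[name]
        return r["min"], r["max"], r.get("scale", "linear")

    priors: list[ParamPrior] = []

    def add(name, template_src, template_name):
        lo, hi, scale = row(template_src, template_name)
        priors.append(ParamPrior(name, float(lo), float(hi), scale))

    for scalar in ("D", "K", "K_omega", "S0", "gamma", "n_omega", "omega_max",
                   "C_N", "C_B", "C_A"):
        add(scalar, pt, scalar)
    for x in range(structure.n_strains):
        add(f"mu_max_{x + 1}", pt, "mu_max")
    for y in structure.qs_systems:
        add(f"kA_{y}", pt, "kA")
    for slot, z in enumerate(structure.bacteriocins):
        y = structure.qs_systems[structure.regulators[slot]]
        add(f"K_A{y}B{z}", pt, "K_AB")
        add(f"KB_max_{z}", pt, "KB_max")
        add(f"n_{z}", pt, "n_z")
    for x in range(structure.n_strains):
        add(f"N_{x + 1}", it, "N")
    add("S", it, "S")
    for z in structure.bacteriocins:
        add(f"B_{z}", it, "B")
    for y in structure.qs_systems:
        add(f"A_{y}", it, "A")
    return PriorSpec(params=tuple(priors))
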