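"""End-to-end search for oscillatory and chaotic community topologies.

Wires the model space, the prior table, the chemostat simulator and the
behaviour objectives into ABC SMC: the oscillation stage scores every
particle with the three-component oscillation distance; the chaos stage
first applies a cheap prescreen (no extinction, at least two sizeable
oscillations per strain) and only then spends time on the dual-orbit
Lyapunov exponent, converting it to the chaos distance 1/(1 + lambda_1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abcsmc import PriorSpec, SMCConfig, SMCResult, community_prior, run_smc
from .core_io import load_prior_config
from .dynamics import CommunityParams, community_rhs, initial_state, simulate
from .lyapunov import LyapunovConfig, max_lyapunov
from .model_space import CommunityModel, ModelSpace, build_equation_structure
from .objectives import (CHAOS_EPS_FINAL, OSCILLATION_EPS_FINAL, DistanceVector,
                         chaos_distance, chaos_prescreen, oscillation_distances)

__all__ = ["CommunitySearch"]


@dataclass
class CommunitySearch:
    """Objective-driven ABC SMC over a collection of community models."""

    models: Mapping[int, CommunityModel]
    prior_config: dict | None = None
    t_end: float = 5000.0
    lyapunov_config: LyapunovConfig | None = None
    _structures: dict = field(default_factory=dict, init=False)
    _priors: dict = field(default_factory=dict, init=False)
    _rhs_cache: dict = field(default_factory=dict, init=False)

    @classmethod
    def from_model_space(cls, space: ModelSpace, **kwargs) -> "CommunitySearch":
        return cls(models={m.model_id: m for m in space}, **kwargs)

    def __post_init__(self) -> None:
        if self.prior_config is None:
            self.prior_config = load_prior_config()
        if self.lyapunov_config is None:
            self.lyapunov_config = LyapunovConfig(t_end=self.t_end)

    # -- cached per-model pieces -------------------------------------------
    def structure(self, model_id: int):
        if model_id not in self._structures:
            self._structures[model_id] = build_equation_structure(self.models[model_id])
        return self._structures[model_id]

    def prior_for_model(self, model_id: int) -> PriorSpec:
        if model_id not in self._priors:
            self._priors[model_id] = community_prior(self.structure(model_id),
                                                     self.prior_config)
        return self._priors[model_id]

    # -- objectives ---------------------------------------------------------
    def simulate_vector(self, model_id: int, vector: Mapping[str, float]):
        structure = self.structure(model_id)
        params = CommunityParams.from_mapping(structure, vector)
        rhs = community_rhs(structure, params)
        y0 = initial_state(structure, vector)
        traj = simulate(rhs, y0, t_end=self.t_end,
                        n_strains=structure.n_strains,
                        state_names=structure.state_names)
        return rhs, y0, traj

    def oscillation_distance(self, model_id: int, vector: Mapping[str, float],
                             rng=None) -> DistanceVector:
        structure = self.structure(model_id)
        _, _, traj = self.simulate_vector(model_id, vector)
        return oscillation_distances(traj, structure.n_strains)

    def chaos_objective_distance(self, model_id: int, vector: Mapping[str, float],
                                 rng=None) -> DistanceVector:
        structure = self.structure(model_id)
        rhs, y0, traj = self.simulate_vector(model_id, vector)
        if not chaos_prescreen(traj, structure.n_strains):
            return DistanceVector.max_distance(1)
        cfg = self.lyapunov_config
        if cfg.n_strains is None:
            from dataclasses import replace
            cfg = replace(cfg, n_strains=structure.n_strains, t_end=self.t_end)
        res = max_lyapunov(rhs, y0, cfg)
        if not res.ok:
            return DistanceVector.max_distance(1)
        return chaos_distance(res.lambda1)

    # -- drivers ------------------------------------------------------------
    def run(self, objective: str = "oscillation",
            config: SMCConfig | None = None,
            rng: np.random.Generator | int | None = None,
            repeats: int = 1) -> SMCResult:
        if objective == "oscillation":
            dist, eps = self.oscillation_distance, OSCILLATION_EPS_FINAL
        elif objective == "chaos":
            dist, eps = self.chaos_objective_distance, CHAOS_EPS_FINAL
        else:
            raise ValueError(f"unknown objective {objective!r}")
        config = config or SMCConfig(t_end=self.t_end)
        return run_smc(sorted(self.models), self.prior_for_model, dist, eps,
                       config=config, rng=rng, repeats=repeats)

    def particles_to_frame(self, result: SMCResult) -> pd.DataFrame:
        """Final-population particles as a table (one column per parameter)."""
        rows = []
        for pop in result._final_populations:
            for p in pop.particles:
                row = {"model_id": p.model_id, "weight": p.weight}
                row.update(self.prior_for_model(p.model_id).as_dict(p.theta))
                rows.append(row)
        return pd.DataFrame(rows)
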