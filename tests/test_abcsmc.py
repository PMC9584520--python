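"""Prior sampling, perturbation kernels, weights and the SMC driver."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from chaoscope.abcsmc import (ParamPrior, Particle, Population, PriorSpec,
                              SMCConfig, community_prior, compute_weight,
                              perturb, run_smc, sample_prior, update_epsilon)
from chaoscope.core_io import load_prior_config
from chaoscope.model_space import build_equation_structure, reference_topology
from chaoscope.objectives import DistanceVector


@pytest.fixture(scope="module")
def uniform_prior():
    return PriorSpec((ParamPrior("theta", 0.0, 1.0),))


class TestPriors:
    def test_constants_always_fixed(self, rng):
        p = ParamPrior("S0", 0.02, 0.02)
        assert all(p.sample(rng) == 0.02 for _ in range(10))

    def test_linear_samples_respect_bounds(self, rng):
        p = ParamPrior("D", 0.01, 0.5)
        draws = np.array([p.sample(rng) for _ in range(10_000)])
        assert draws.min() >= 0.01 and draws.max() <= 0.5
        # uniform coverage: both halves populated
        assert 0.3 < (draws < 0.255).mean() < 0.7

    def test_log_scale_spreads_over_decades(self, rng):
        p = ParamPrior("kA", 1e-22, 1e-15, scale="log10")
        draws = np.array([p.sample(rng) for _ in range(10_000)])
        assert draws.min() >= 1e-22 and draws.max() <= 1e-15
        # log-uniform: about half the draws below the geometric midpoint
        mid = 10 ** (0.5 * (np.log10(1e-22) + np.log10(1e-15)))
        assert 0.45 < (draws < mid).mean() < 0.55

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamPrior("x", 1.0, 0.5)

    def test_community_prior_covers_model_parts(self):
        structure = build_equation_structure(reference_topology())
        prior = community_prior(structure, load_prior_config())
        names = set(prior.names)
        for required in ("D", "mu_max_1", "mu_max_2", "mu_max_3", "kA_1",
                         "KB_max_1", "KB_max_2", "K_A1B1", "K_A1B2",
                         "n_1", "n_2", "N_1", "S", "B_1", "B_2", "A_1"):
            assert required in names

    def test_single_model_space_sampling(self, uniform_prior, rng):
        for _ in range(5):
            p = sample_prior([7], lambda m: uniform_prior, rng)
            assert p.model_id == 7


class TestPerturb:
    def test_zero_width_kernel_is_identity(self, uniform_prior, rng):
        base = Particle(model_id=0, theta=np.array([0.3]))
        out = perturb(base, [0], lambda m: uniform_prior, rng,
                      kernel_factor=0.0, p_model=0.0)
        assert out.theta[0] == 0.3

    def test_boundary_particle_stays_in_support(self, uniform_prior, rng):
        base = Particle(model_id=0, theta=np.array([1.0]))
        for _ in range(10_000):
            out = perturb(base, [0], lambda m: uniform_prior, rng, p_model=0.0)
            assert 0.0 <= out.theta[0] <= 1.0

    def test_model_switch_probability(self, uniform_prior, rng):
        base = Particle(model_id=0, theta=np.array([0.5]))
        never = [perturb(base, [0, 1], lambda m: uniform_prior, rng, p_model=0.0)
                 for _ in range(200)]
        assert all(p.model_id == 0 for p in never)
        always = [perturb(base, [0, 1], lambda m: uniform_prior, rng, p_model=1.0)
                  for _ in range(200)]
        assert all(p.model_id == 1 for p in always)


class TestWeights:
    def test_generation_zero_weight_is_one(self, uniform_prior):
        p = Particle(model_id=0, theta=np.array([0.5]))
        assert compute_weight(p, None, lambda m: uniform_prior, generation=0) == 1.0

    def test_single_previous_particle_gives_constant_weight(self, uniform_prior):
        prev = Population(particles=[Particle(0, np.array([0.5]), weight=1.0)],
                          eps=(np.inf,), t=0)
        # for a uniform prior and symmetric kernel, the weight is the same for
        # every in-support proposal the kernel can reach
        w = [compute_weight(Particle(0, np.array([v])), prev,
                            lambda m: uniform_prior, generation=1)
             for v in (0.45, 0.5, 0.55)]
        assert w[0] == pytest.approx(w[1]) == pytest.approx(w[2])

    def test_out_of_support_proposal_gets_zero_weight(self, uniform_prior):
        prev = Population(particles=[Particle(0, np.array([0.5]), weight=1.0)],
                          eps=(np.inf,), t=0)
        w = compute_weight(Particle(0, np.array([1.5])), prev,
                           lambda m: uniform_prior, generation=1)
        assert w == 0.0

    def test_kernel_support_violation_raises(self, uniform_prior):
        prev = Population(particles=[Particle(0, np.array([0.0]), weight=1.0)],
                          eps=(np.inf,), t=0)
        with pytest.raises(ZeroDivisionError):
            compute_weight(Particle(0, np.array([0.9])), prev,
                           lambda m: uniform_prior, generation=1)


class TestEpsilonSchedule:
    def test_lower_quantile_convention(self):
        eps, final = update_epsilon(np.array([[1.0], [2.0], [3.0], [4.0]]),
                                    alpha=0.5, eps_final=[0.1])
        assert eps == (2.0,)
        assert not final

    def test_floor_at_final_threshold(self):
        eps, final = update_epsilon(np.array([[0.01], [0.02]]), alpha=0.5,
                                    eps_final=[0.05])
        assert eps == (0.05,)
        assert final

    def test_alpha_one_keeps_maximum(self):
        eps, _ = update_epsilon(np.array([[1.0], [5.0], [3.0]]), alpha=1.0,
                                eps_final=[0.1])
        assert eps == (5.0,)

    def test_never_increases(self):
        eps, _ = update_epsilon(np.array([[9.0], [8.0]]), alpha=0.5,
                                eps_final=[0.1], eps_current=[4.0])
        assert eps == (4.0,)


class TestDriver:
    def test_toy_posterior_matches_rejection_oracle(self, uniform_prior):
        """|theta - 0.5| < 0.05 has a uniform posterior on (0.45, 0.55)."""

        def dist(mid, th, rng):
            return DistanceVector((abs(th["theta"] - 0.5),))

        res = run_smc([0], lambda m: uniform_prior, dist, eps_final=(0.05,),
                      config=SMCConfig(pop_size=500, max_generations=12), rng=3)
        assert res.status == "converged"
        pop = res.final_population
        # every accepted distance beats the final threshold
        assert np.all(pop.distance_matrix < 0.05)
        # epsilon schedule shrinks monotonically
        eps = [p.eps[0] for p in res.populations]
        assert all(b <= a for a, b in zip(eps, eps[1:]))
        # generation-0 weights are all equal; all weights normalised
        assert np.allclose(res.populations[0].weights, 1.0 / 500)
        for p in res.populations:
            assert np.isclose(p.weights.sum(), 1.0)
        # posterior equals the rejection-ABC oracle
        oracle_rng = np.random.default_rng(7)
        oracle = oracle_rng.uniform(0, 1, 200_000)
        oracle = oracle[np.abs(oracle - 0.5) < 0.05]
        theta = np.array([p.theta[0] for p in pop.particles])
        w = pop.weights
        resampled = np.random.default_rng(11).choice(theta, size=2000,
                                                     p=w / w.sum())
        assert ks_2samp(resampled, oracle).statistic < 0.1
        assert abs(np.average(theta, weights=w) - 0.5) < 0.01

    def test_unreachable_model_loses_all_posterior_mass(self, uniform_prior):
        """Model 1's distances can never beat eps_F, so mass flows to model 0."""

        def dist(mid, th, rng):
            base = abs(th["theta"] - 0.5)
            return DistanceVector((base if mid == 0 else base + 1.0,))

        res = run_smc([0, 1], lambda m: uniform_prior, dist, eps_final=(0.05,),
                      config=SMCConfig(pop_size=100, max_generations=12), rng=5)
        post = res.model_posterior().set_index("model_id")
        assert post.loc[0, "posterior_mean"] == pytest.approx(1.0)
        assert post.loc[1, "posterior_mean"] == 0.0

    def test_repeats_pool_final_populations(self, uniform_prior):
        def dist(mid, th, rng):
            return DistanceVector((abs(th["theta"] - 0.5),))

        res = run_smc([0], lambda m: uniform_prior, dist, eps_final=(0.2,),
                      config=SMCConfig(pop_size=20, max_generations=8),
                      rng=1, repeats=3)
        assert len(res._final_populations) == 3
        post = res.model_posterior()
        assert post["posterior_mean"].iloc[0] == pytest.approx(1.0)
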