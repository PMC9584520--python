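"""Fixed points of the reference topology: closed forms, roots, stability."""

import numpy as np
import pytest

from chaoscope import (CommunityParams, coexistence_conditions, community_rhs,
                       find_coexistence_state, simulate, single_strain_states,
                       trivial_state)
from chaoscope.steady_state import _jacobian_eigs, numerical_jacobian


@pytest.fixture(scope="module")
def params(reference_structure, reference_vector):
    return CommunityParams.from_mapping(reference_structure, reference_vector)


class TestWashoutState:
    def test_closed_form_eigenvalues_match_numerical_jacobian(self, params):
        state, report = trivial_state(params)
        numeric = np.sort(_jacobian_eigs(params, state.coordinates).real)
        analytic = np.sort(report.eigenvalues.real)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-10)

    def test_dilution_eigenvalue_present(self, params):
        _, report = trivial_state(params)
        assert np.isclose(report.eigenvalues.real, -0.167).any()

    def test_unstable_at_reference_dilution(self, params):
        # D = 0.167 is far below the fastest washout limit (~2.6/h)
        state, report = trivial_state(params)
        assert state.exists
        assert not report.stable
        cond = report.analytic_conditions["D > S0/(S0+K) * max(mu_max)"]
        assert not cond["satisfied"]

    def test_stable_when_dilution_beats_growth(self, reference_structure,
                                               reference_vector):
        vec = dict(reference_vector)
        for x in (1, 2, 3):
            vec[f"mu_max_{x}"] = 0.1
        p = CommunityParams.from_mapping(reference_structure, vec)
        _, report = trivial_state(p)
        assert report.stable


class TestSingleSurvivors:
    def test_survivor2_substrate_closed_form(self, params):
        states = single_strain_states(params)
        s2, _ = states["P2"]
        assert s2.exists
        expected = params.D * params.K / (params.mu_max[1] - params.D)
        assert s2.coordinates[3] == pytest.approx(expected, rel=1e-12)
        assert s2.coordinates[3] == pytest.approx(6.49e-6, rel=0.01)

    def test_survivor2_density_matches_long_time_simulation(self, params,
                                                            reference_structure):
        s2, _ = single_strain_states(params)["P2"]
        rhs = community_rhs(reference_structure, params)
        y0 = np.array([0.0, 0.3, 0.0, params.S0, 0.0, 0.0, 0.0])
        traj = simulate(rhs, y0, t_end=2000.0, extinction_threshold=None)
        np.testing.assert_allclose(traj.states[-1, 1], s2.coordinates[1],
                                   rtol=1e-3)

    @pytest.mark.parametrize("label", ["P2", "P3"])
    def test_closed_form_eigenvalues_match_numerics(self, params, label):
        state, report = single_strain_states(params)[label]
        numeric = np.sort(_jacobian_eigs(params, state.coordinates).real)
        analytic = np.sort(report.eigenvalues.real)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)

    def test_survivors_unstable_because_not_fastest(self, params):
        # mu_max2 = 1.17 and mu_max3 = 1.48 are both below mu_max1 = 2.61
        states = single_strain_states(params)
        assert not states["P2"][1].stable
        assert not states["P3"][1].stable

    def test_survivor1_exists_with_small_residual(self, params):
        s1, report = single_strain_states(params)["P1"]
        assert report.analytic_conditions["D < mu_max1*S0/(K+S0)"]["satisfied"]
        assert s1.exists
        assert s1.residual < 1e-8
        assert np.all(s1.coordinates[[0, 4, 6]] > 0)   # N1, B1, A1 positive

    def test_survivor1_existence_dichotomy_over_dilution_sweep(self,
                                                               reference_structure,
                                                               reference_vector):
        """The scalar-balance root exists exactly when the dilution rate is
        below strain 1's washout limit, across a sweep of D."""
        vec = dict(reference_vector)
        mu1 = vec["mu_max_1"]
        limit = mu1 * vec["S0"] / (vec["K"] + vec["S0"])
        hits = 0
        for D in np.linspace(0.01, 2 * limit, 100):
            vec["D"] = float(D)
            p = CommunityParams.from_mapping(reference_structure, vec)
            s1, _ = single_strain_states(p)["P1"]
            assert s1.exists == (D < limit)
            hits += s1.exists
        assert 0 < hits < 100


class TestCoexistence:
    def test_condition_margins_at_reference_point(self, params):
        rec = coexistence_conditions(params)
        assert rec["satisfied"]
        # lower bound terms: washout bound and the two killing bounds
        assert rec["lower < mu_max2"]["lhs"] == pytest.approx(0.4555, rel=1e-3)
        assert rec["lower < mu_max2"]["rhs"] == 1.17
        assert rec["mu_max2 < min(mu_max1, mu_max3)"]["rhs"] == pytest.approx(1.48)
        assert rec["substrate"]["S"] == pytest.approx(6.4935e-6, rel=1e-4)

    def test_violated_when_middle_strain_grows_fastest(self, reference_structure,
                                                       reference_vector):
        vec = dict(reference_vector)
        vec["mu_max_2"] = 2.9   # faster than both competitors
        p = CommunityParams.from_mapping(reference_structure, vec)
        rec = coexistence_conditions(p)
        assert not rec["satisfied"]
        assert not rec["mu_max2 < min(mu_max1, mu_max3)"]["satisfied"]

    def test_interior_state_found_with_small_residual(self, params,
                                                      reference_structure):
        state, report = find_coexistence_state(params)
        assert state.exists
        assert state.residual < 1e-8
        assert np.all(state.coordinates[:3] > 0)
        # the unkilled strain pins the substrate
        expected_S = params.D * params.K / (params.mu_max[1] - params.D)
        assert state.coordinates[3] == pytest.approx(expected_S, rel=1e-8)
        rhs = community_rhs(reference_structure, params)
        np.testing.assert_allclose(rhs(0.0, state.coordinates), 0.0, atol=1e-8)

    def test_interior_state_exists_across_nearby_vectors(self, reference_structure,
                                                         reference_vector, rng):
        """Coexistence root persists over a small cloud around the reference
        vector (the desk-scale analogue of its ubiquity in posterior samples)."""
        found = 0
        for _ in range(5):
            vec = dict(reference_vector)
            vec["D"] *= float(rng.uniform(0.95, 1.05))
            vec["kA_1"] *= float(rng.uniform(0.8, 1.25))
            vec["mu_max_2"] *= float(rng.uniform(0.97, 1.03))
            p = CommunityParams.from_mapping(reference_structure, vec)
            if not coexistence_conditions(p)["satisfied"]:
                continue
            state, _ = find_coexistence_state(p)
            assert state.exists and state.residual < 1e-8
            found += 1
        assert found >= 3

    def test_stable_state_attracts_nearby_trajectories(self, reference_structure,
                                                       reference_vector):
        """In the weak-QS regime the interior state is stable; a slightly
        perturbed trajectory must stay close to it."""
        vec = dict(reference_vector)
        vec["kA_1"] = 1.5e-18
        p = CommunityParams.from_mapping(reference_structure, vec)
        state, report = find_coexistence_state(p)
        assert state.exists and report.stable
        rhs = community_rhs(reference_structure, p)
        y0 = state.coordinates * (1 + 1e-6)
        traj = simulate(rhs, y0, t_end=1000.0, n_strains=3)
        assert traj.termination.completed
        drift = np.abs(traj.states[-1, :3] - state.coordinates[:3])
        assert np.all(drift < 1e-3)


def test_numerical_jacobian_on_quadratic_map():
    f = lambda y: np.array([y[0] ** 2, y[0] * y[1]])
    J = numerical_jacobian(f, np.array([2.0, 3.0]))
    np.testing.assert_allclose(J, [[4.0, 0.0], [3.0, 2.0]], rtol=1e-7)
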