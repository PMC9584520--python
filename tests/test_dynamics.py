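"""Rate laws, right-hand sides and trajectory integration."""

import numpy as np
import pytest

from chaoscope import (CommunityParams, GLVParams, bacteriocin_expression,
                       community_rhs, glv_rhs, initial_state, kill_rate,
                       monod_growth, simulate)


class TestRateLaws:
    @pytest.mark.parametrize("mu_max,S,K,expected", [
        (2.0, 3.9e-5, 3.9e-5, 1.0),                      # half saturation
        (1.5, 0.0, 3.9e-5, 0.0),                         # no substrate
        (1.17, 0.02, 3.9e-5, 1.17 * 0.02 / 0.020039),    # fixed-vector values
    ])
    def test_monod(self, mu_max, S, K, expected):
        assert monod_growth(mu_max, S, K) == pytest.approx(expected, rel=1e-12)

    def test_monod_rejects_negative_substrate(self):
        with pytest.raises(ValueError):
            monod_growth(1.0, -1e-3, 3.9e-5)

    def test_monod_monotone_and_bounded(self):
        S = np.linspace(0, 1, 50)
        v = monod_growth(2.0, S, 3.9e-5)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < 2.0)

    def test_kill_rate_half_max_and_insensitive(self):
        assert kill_rate(0.8, 1.6e-7, 1.6e-7, 1.87) == pytest.approx(0.4)
        assert kill_rate(0.8, 1.0, 1.6e-7, 1.87, sensitive=False) == 0.0
        assert kill_rate(0.8, 1e9, 1.6e-7, 1.87) == pytest.approx(0.8, rel=1e-6)

    def test_expression_hill_forms(self):
        # induced: half-max at the regulation constant, zero without signal
        assert bacteriocin_expression(1e-16, 3.37e-9, 3.37e-9, 1.2, "induced") \
            == pytest.approx(0.5e-16)
        assert bacteriocin_expression(1e-16, 0.0, 3.37e-9, 1.2, "induced") == 0.0
        # repressed: full expression without signal
        assert bacteriocin_expression(1e-16, 0.0, 3.37e-9, 1.2, "repressed") \
            == pytest.approx(1e-16)


class TestCommunityRHS:
    def test_matches_hand_coded_reference_equations(self, reference_structure, reference_params,
                                                    reference_rhs, rng):
        """Dual-implementation oracle: the seven equations of the reference
        topology coded directly, without the structure machinery."""
        p = reference_params

        def handcoded(y):
            N1, N2, N3, S, b1, b2, a1 = y
            mu = [p.mu_max[i] * S / (p.K + S) for i in range(3)]
            def omega(b):
                Bn = (b * p.C_B) ** p.n_omega
                return p.omega_max * Bn / (p.K_omega ** p.n_omega + Bn)
            def k_B(slot, a):
                An = (a * p.C_A) ** p.n_z[slot]
                return p.KB_max[slot] * An / (p.K_AB[slot] ** p.n_z[slot] + An)
            dN1 = N1 * mu[0] - N1 * omega(b1) - N1 * p.D
            dN2 = N2 * mu[1] - N2 * p.D
            dN3 = N3 * mu[2] - N3 * omega(b2) - N3 * p.D
            dS = p.D * (p.S0 - S) - sum(mu[i] * y[i] for i in range(3)) * p.C_N / p.gamma
            dB1 = k_B(0, a1) * (N1 + N2) * p.C_N / p.C_B - p.D * b1
            dB2 = k_B(1, a1) * N3 * p.C_N / p.C_B - p.D * b2
            dA1 = p.kA[0] * N1 * p.C_N / p.C_A - p.D * a1
            return np.array([dN1, dN2, dN3, dS, dB1, dB2, dA1])

        scales = np.array([1.0, 1.0, 1.0, 0.02, 50.0, 50.0, 50.0])
        for _ in range(10):
            y = rng.uniform(0.01, 1.0, 7) * scales
            np.testing.assert_allclose(reference_rhs(0.0, y), handcoded(y), rtol=1e-10)

    def test_fast_and_reference_paths_agree(self, reference_rhs, rng):
        ref = getattr(reference_rhs, "reference", None)
        if ref is None:
            pytest.skip("compiled path not in use")
        for _ in range(5):
            y = rng.uniform(0.0, 2.0, 7)
            np.testing.assert_allclose(reference_rhs(0.0, y), ref(0.0, y), rtol=1e-12)

    def test_dead_community_relaxes_to_feed(self, reference_structure, reference_params, reference_rhs):
        y = np.array([0.0, 0.0, 0.0, 0.01, 5.0, 3.0, 2.0])
        d = reference_rhs(0.0, y)
        p = reference_params
        assert d[3] == pytest.approx(p.D * (p.S0 - 0.01))
        np.testing.assert_allclose(d[4:], -p.D * y[4:])
        # substrate already at feed level: no net change
        y2 = np.array([0.0, 0.0, 0.0, p.S0, 0.0, 0.0, 0.0])
        assert reference_rhs(0.0, y2)[3] == 0.0


class TestGLV:
    def test_zero_state_is_fixed(self):
        p = GLVParams(r=[1.0, 0.7], alpha=[[1.0, 0.2], [0.3, 1.0]])
        np.testing.assert_array_equal(glv_rhs(p)(0.0, np.zeros(2)), np.zeros(2))

    def test_logistic_closed_form(self):
        # n = 1 with unit self-interaction: N(t) = N0 e^t / (1 + N0(e^t - 1))
        p = GLVParams(r=[1.0], alpha=[[1.0]])
        traj = simulate(glv_rhs(p), [0.05], t_end=10.0, dt_out=0.1,
                        extinction_threshold=None, rtol=1e-10, atol=1e-12)
        t = traj.times
        exact = 0.05 * np.exp(t) / (1 + 0.05 * (np.exp(t) - 1.0))
        np.testing.assert_allclose(traj.states[:, 0], exact, rtol=1e-6)

    def test_chaotic_attractor_rhs_value(self, glv_attractor):
        params, y0 = glv_attractor
        expected = params.r * y0 * (1.0 - params.alpha @ y0)
        np.testing.assert_allclose(glv_rhs(params)(0.0, y0), expected, rtol=1e-14)


class TestSimulate:
    def test_reference_vector_completes_with_sustained_oscillations(self, reference_trajectory):
        traj = reference_trajectory
        assert traj.termination.completed
        assert traj.times[-1] == pytest.approx(5000.0)
        # the community keeps cycling to the end: the two large strains swing
        # by ~0.1 OD while the killed strain participates at small amplitude
        # but never approaches washout
        for x in (1, 2):
            tail = traj.strain(x)[-1500:]
            assert tail.max() - tail.min() > 0.05
        assert traj.strain(0).min() > 1e-5

    def test_nonnegativity_and_substrate_bound(self, reference_trajectory, reference_params):
        assert np.min(reference_trajectory.states) > -1e-6
        S = reference_trajectory.column("S")
        assert S.max() <= max(S[0], reference_params.S0) + 1e-6

    def test_washout_extinction(self, reference_structure, reference_vector):
        # growth too slow to beat dilution anywhere: every strain washes out
        vec = dict(reference_vector)
        for x in (1, 2, 3):
            vec[f"mu_max_{x}"] = 0.1
        params = CommunityParams.from_mapping(reference_structure, vec)
        rhs = community_rhs(reference_structure, params)
        traj = simulate(rhs, initial_state(reference_structure, vec), t_end=5000.0,
                        n_strains=3)
        assert traj.termination.status == "extinction"
        assert traj.termination.time < 200.0
        assert traj.termination.strain in (0, 1, 2)

    def test_single_survivor_substrate_level(self, reference_structure, reference_vector):
        # strain 2 alone pins the substrate at D K / (mu_max2 - D)
        vec = dict(reference_vector)
        vec["N_1"] = 0.0
        vec["N_3"] = 0.0
        params = CommunityParams.from_mapping(reference_structure, vec)
        rhs = community_rhs(reference_structure, params)
        traj = simulate(rhs, initial_state(reference_structure, vec), t_end=3000.0,
                        extinction_threshold=None)
        expected = params.D * params.K / (params.mu_max[1] - params.D)
        assert traj.states[-1, 3] == pytest.approx(expected, rel=1e-3)

    def test_tolerance_stability_of_nonchaotic_endpoint(self, reference_structure,
                                                        reference_vector):
        # weak QS production -> damped dynamics; endpoint must be solver-robust
        vec = dict(reference_vector)
        vec["kA_1"] = 2e-18
        params = CommunityParams.from_mapping(reference_structure, vec)
        rhs = community_rhs(reference_structure, params)
        y0 = initial_state(reference_structure, vec)
        a = simulate(rhs, y0, t_end=2000.0, n_strains=3)
        b = simulate(rhs, y0, t_end=2000.0, n_strains=3, rtol=1e-5, atol=1e-10)
        assert a.termination.completed and b.termination.completed
        rel = np.abs(a.states[-1] - b.states[-1]) / np.maximum(np.abs(b.states[-1]), 1e-12)
        assert np.max(rel) < 1e-3

    def test_rejects_negative_initial_state(self, reference_rhs):
        with pytest.raises(ValueError):
            simulate(reference_rhs, [-0.1, 0.2, 0.2, 0.02, 0, 0, 0])
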