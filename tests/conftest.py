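"""Shared fixtures: the reference chaotic community and gLV benchmark.

Expensive artefacts (the 5000 h reference trajectory and its Lyapunov
exponent) are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from chaoscope import (CommunityParams, LyapunovConfig, community_rhs,
                       initial_state, load_fixed_params, load_glv_attractor,
                       reference_topology, max_lyapunov, simulate)
from chaoscope.model_space import build_equation_structure


@pytest.fixture(scope="session")
def reference_model():
    return reference_topology()


@pytest.fixture(scope="session")
def reference_structure(reference_model):
    return build_equation_structure(reference_model)


@pytest.fixture(scope="session")
def reference_vector():
    """Fixed parameter vector plus initial state of the chaotic benchmark."""
    pars, init = load_fixed_params()
    return {**pars, **init}


@pytest.fixture(scope="session")
def reference_params(reference_structure, reference_vector):
    return CommunityParams.from_mapping(reference_structure, reference_vector)


@pytest.fixture(scope="session")
def reference_rhs(reference_structure, reference_params):
    return community_rhs(reference_structure, reference_params)


@pytest.fixture(scope="session")
def reference_y0(reference_structure, reference_vector):
    return initial_state(reference_structure, reference_vector)


@pytest.fixture(scope="session")
def reference_trajectory(reference_rhs, reference_y0, reference_structure):
    return simulate(reference_rhs, reference_y0, t_end=5000.0, n_strains=3,
                    state_names=reference_structure.state_names)


@pytest.fixture(scope="session")
def reference_lyapunov(reference_rhs, reference_y0):
    return max_lyapunov(reference_rhs, reference_y0,
                        LyapunovConfig(t_end=5000.0, n_strains=3))


@pytest.fixture(scope="session")
def glv_attractor():
    return load_glv_attractor()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
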