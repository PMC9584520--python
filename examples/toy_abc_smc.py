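"""ABC SMC on a transparent toy problem with a known posterior.

Accepting |theta - 0.5| < 0.05 under a U(0,1) prior gives a posterior that
is exactly U(0.45, 0.55); the SMC machinery should reproduce it through a
shrinking threshold schedule.
"""
import numpy as np
from chaoscope import ParamPrior, PriorSpec, SMCConfig, run_smc
from chaoscope.objectives import DistanceVector

prior = PriorSpec((ParamPrior("theta", 0.0, 1.0),))
dist = lambda mid, th, rng: DistanceVector((abs(th["theta"] - 0.5),))
res = run_smc([0], lambda m: prior, dist, eps_final=(0.05,),
              config=SMCConfig(pop_size=300, max_generations=12), rng=1)

pop = res.final_population
theta = np.array([p.theta[0] for p in pop.particles])
print(f"status: {res.status}")
print("epsilon schedule:", [round(float(p.eps[0]), 4) for p in res.populations])
print(f"posterior mean = {np.average(theta, weights=pop.weights):.4f} "
      f"(expected 0.5000)")
print(f"posterior range = [{theta.min():.3f}, {theta.max():.3f}] "
      "(expected ~[0.450, 0.550])")
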