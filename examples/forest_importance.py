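"""Which parameters separate oscillation from chaos? A random-forest view.

Builds a synthetic labelled set of input vectors in which only the dilution
rate carries the class signal, trains an entropy-criterion forest, and
ranks features by mean information gain.
"""
import numpy as np
import pandas as pd
from chaoscope import build_dataset, feature_importance, train_classifier

rng = np.random.default_rng(0)
def vectors(n, low_D):
    D = rng.uniform(0.01, 0.2, n) if low_D else rng.uniform(0.2, 0.5, n)
    return pd.DataFrame({"D": D,
                         "kA_1": 10 ** rng.uniform(-18, -16, n),
                         "mu_max_2": rng.uniform(1.0, 3.0, n)})

ds = build_dataset(vectors(400, True), vectors(400, False), seed=1)
fit = train_classifier(ds, n_trees=500, seed=1)
print(f"test accuracy: {fit['accuracy']:.3f}")
print(feature_importance(fit["model"], ds.feature_names).to_string(index=False))
print("The forest recovers the planted signal: D dominates the information")
print("gain while the uninformative features share the remainder.")
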