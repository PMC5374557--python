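"""The crystal-resolution effect on cross-validated prediction accuracy.

Generates a dataset in which the features that determine affinity are
measured with noise that grows for structures solved worse than 2.5 A,
then compares pooled leave-one-out cross-validated accuracy of a model
trained on the high-resolution stratum against the full mixture, and
against a random subset of the same size (the control showing the gain
is not a sample-size artifact).
"""

import numpy as np

from ppaffinity import generate_resolution_effect_dataset, glm_procedure, loo_cv
from ppaffinity.glm import ModelSpec

seed = 11
X, y, metadata, truth, highres = generate_resolution_effect_dataset(seed=seed)
y = np.asarray(y)
spec = ModelSpec(frozenset(X.columns))

full = loo_cv(X, y, glm_procedure(spec), n_replicates=100, seed=seed)
strat = loo_cv(X.iloc[highres], y[highres], glm_procedure(spec), n_replicates=100, seed=seed)

rng = np.random.default_rng(seed)
idx = rng.choice(len(X), size=int(highres.sum()), replace=False)
rand = loo_cv(X.iloc[idx], y[idx], glm_procedure(spec), n_replicates=100, seed=seed)

print(f"n = {len(X)} complexes, {highres.sum()} with resolution <= 2.5 A\n")
print(f"full mixture          r2 = {full.r2:.3f}   RMSD = {full.rmsd:.2f} pKd")
print(f"high-res stratum      r2 = {strat.r2:.3f}   RMSD = {strat.rmsd:.2f} pKd")
print(f"random equal subset   r2 = {rand.r2:.3f}   RMSD = {rand.rmsd:.2f} pKd")
print(
    "\nThe stratum improves on the mixture because its features are less "
    "degraded; the random subset, which shares only the smaller size, does not."
)
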