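"""Learn a context-specific-independence structure with structural EM.

Plants a 5-component, 4-feature Gaussian model in which some features share
parameters across subsets of components (one feature is fully shared, one
fully distinct), samples n=2000, and lets structural EM rediscover which
components share which features.  The printed matrix shows one letter per
(component, feature) cell: cells with the same letter in a column share one
parameter set."""

import numpy as np

from hetmix import (CSIMixtureModel, CSIStructure, EMSettings,
                    GaussianDistribution, merge_redundant_components,
                    sample_dataset)
from hetmix.csi import rand_max_structural_em

plant = [
    [(0, 1), (2,), (3, 4)],      # partial sharing
    [(0,), (1, 2, 3), (4,)],     # middle components share
    [(0, 1, 2, 3, 4)],           # uninformative: fully shared
    [(0,), (1,), (2,), (3,), (4,)],  # fully distinct
]
dists = [[GaussianDistribution(4.0 * b, 1.0) for b in range(len(part))]
         for part in plant]
true = CSIMixtureModel(np.full(5, 0.2), CSIStructure(plant, dists))

data, _ = sample_dataset(true, 2000, seed=3)
template = CSIMixtureModel.from_mixture(true.expand())
fitted, trace = rand_max_structural_em(
    template, data,
    EMSettings(max_iter=150, loglik_tol=1e-6, seed=0, n_restarts=5))

print("planted structure:")
print(true.structure.render())
print("\nlearned structure (components may be permuted):")
print(fitted.structure.render())
print(f"\nfree parameters: learned {fitted.n_parameters()} vs "
      f"conventional mixture {template.n_parameters()}")
merged = merge_redundant_components(fitted)
print(f"components after merging fully identified ones: {merged.K}")
print("matching column patterns (up to row order and letter names) mean "
      "the sharing structure was recovered; the fully shared column "
      "collapses to a single letter.")
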