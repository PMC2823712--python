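"""Fit a two-component Gaussian mixture with EM restarts and recover the
generating parameters.

Samples n=1000 points from 0.4·N(−3,1) + 0.6·N(3,1), runs EM from five
random starts, and prints the recovered weights and means — they should
land within a few hundredths of the generating values."""

import numpy as np

from hetmix import (EMSettings, GaussianDistribution, MixtureModel,
                    ProductComponent, classify, rand_max_em, sample_dataset)

true = MixtureModel([0.4, 0.6], [
    ProductComponent([GaussianDistribution(-3.0, 1.0)]),
    ProductComponent([GaussianDistribution(3.0, 1.0)])])

data, labels = sample_dataset(true, 1000, seed=42)
settings = EMSettings(max_iter=200, loglik_tol=1e-7, seed=0, n_restarts=5)
fitted, trace = rand_max_em(true, data, settings)

order = np.argsort([c.feature_dists[0].mean for c in fitted.components])
print(f"converged after {trace.n_iter} iterations, "
      f"final log likelihood {trace.final_loglik:.2f}")
for rank, k in enumerate(order):
    g = fitted.components[k].feature_dists[0]
    print(f"component {rank}: weight {fitted.pi[k]:.3f}, "
          f"mean {g.mean:+.3f}, stdev {g.stdev:.3f}")

assignment = classify(fitted, data)
agreement = np.mean(assignment.labels[labels == labels] ==
                    assignment.labels)
acc = max(np.mean(assignment.labels == labels),
          np.mean(assignment.labels == 1 - labels))
print(f"cluster/label agreement (up to permutation): {acc:.3f}")
print("weights ≈ (0.4, 0.6) and means ≈ (−3, +3) mean the mixture was "
      "identified; agreement near 1 means the posterior separates the "
      "clusters.")
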