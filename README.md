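# hetmix

Model-based clustering of heterogeneous biological data with finite
mixture models.

Biological datasets — aligned sequences, expression profiles, phenotype
tables — are noisy, partly missing, and mix discrete with continuous
measurements. `hetmix` clusters such data with a **K-component mixture
density**

```
P(x | Θ) = Σₖ πₖ · P(x | θₖ),        Σₖ πₖ = 1,  πₖ ≥ 0
```

whose components are, by default, naive-Bayes products of per-feature
distributions (Gaussian, categorical, exponential):

```
P(x | θₖ) = Πⱼ P(xⱼ | θₖⱼ)
```

Parameters are estimated with the EM algorithm: the E-step computes each
sample's component-membership posterior `P(k | xᵢ, Θ)` by Bayes' rule, the
M-step re-fits π and all component parameters by responsibility-weighted
maximum likelihood, and samples are finally assigned to `argmaxₖ P(k | xᵢ, Θ)`
(optionally left unassigned when the posterior entropy is too high).

On top of the basic model the package implements three extensions:

- **Context-specific independence (CSI) mixtures** — for each feature, the
  K components are partitioned into parameter-sharing blocks; the partition
  is learned inside EM (structural EM) with a BIC-style penalized score.
  The learned sharing matrix shows which features distinguish which
  clusters, and components that share every feature are merged, shrinking K
  automatically.
- **Mixtures of dependence trees** — components are directed-tree
  factorizations `P(x) = P(x_root) Πⱼ P(xⱼ | x_pa(j))` with conditional
  Gaussians or conditional probability tables; each component's topology is
  re-estimated at every EM iteration as the maximum-weight spanning tree of
  its responsibility-weighted mutual-information graph (the Chow–Liu
  construction).
- **Semi-supervised estimation** — partial hard labels (clamped posteriors)
  or soft pairwise positive/negative constraints `w⁺, w⁻ ∈ [0,1]` with
  penalty weights λ⁺, λ⁻ that tilt the posterior against expected
  constraint violations; hard labels are the binary λ→∞ special case.

Fixed-length FASTA files (one discrete feature per position) and delimited
tables with missing values are read directly, and a built-in sampler
generates datasets from any model, so everything can be exercised without
external data.

## Worked example

```python
import numpy as np
from hetmix import (MixtureModel, ProductComponent, GaussianDistribution,
                    EMSettings, sample_dataset, rand_max_em, classify)

true = MixtureModel([0.4, 0.6], [
    ProductComponent([GaussianDistribution(-3.0, 1.0)]),
    ProductComponent([GaussianDistribution(3.0, 1.0)])])

data, labels = sample_dataset(true, 1000, seed=42)
fitted, trace = rand_max_em(
    true, data, EMSettings(max_iter=200, loglik_tol=1e-7, seed=0,
                           n_restarts=5))
```

Running this (it is `examples/01_naive_bayes_mixture.py`) prints

```
converged after 76 iterations, final log likelihood -2101.81
component 0: weight 0.402, mean -3.000, stdev 0.997
component 1: weight 0.598, mean +2.868, stdev 1.027
cluster/label agreement (up to permutation): 1.000
```

The fitted weights (0.402, 0.598) and means (−3.00, +2.87) recover the
generating values π = (0.4, 0.6) and μ = (−3, +3); the agreement line says
the argmax assignment reproduces the generating partition exactly.

The other scripts in `examples/` walk through each capability: FASTA
sequence clustering with feature ranking, CSI structure learning,
dependence-tree mixtures, and semi-supervised estimation.

## Command line

A thin CLI wraps the library for shell use:

```bash
hetmix simulate --model truth.model.json -n 100 --seed 1 --out-prefix sim
hetmix cluster  --input sim.fa -k 2 --family csi --seed 1 --out-prefix run
hetmix classify --model run.model.json --input new.fa --out new.tsv
```

`cluster` writes a JSON model document, a clustering TSV (id, label,
posterior), the per-iteration objective, a structure report (CSI sharing
matrix or per-component tree edges) and a feature-relevance ranking.
Identical invocations with the same seed produce byte-identical outputs.

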