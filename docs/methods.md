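# Methods

This note documents the statistical models implemented in `hetmix`, the
estimation machinery and its numerical choices, the synthetic data the test
suite relies on, and the design decisions taken where more than one
reasonable construction exists.

## Mixture model and EM

The core object is the finite mixture `P(x|Θ) = Σₖ πₖ P(x|θₖ)` over p
features, with naive-Bayes product components by default. Per-feature
distributions are univariate Gaussian (mean, stdev), categorical over an
explicit symbol alphabet, and exponential; the exponential is
**rate-parameterized** (density `r·e^{−rx}`), the convention that makes the
weighted MLE a simple ratio `Σw / Σwx`.

Estimation alternates the exact E-step (responsibilities by Bayes' rule,
computed in log space throughout with log-sum-exp normalization — products
over hundreds of features underflow otherwise) with weighted
maximum-likelihood M-steps. Assignments are `argmax` of the posterior with
ties broken toward the lowest component index; an optional entropy gate
leaves a sample unassigned when its posterior entropy divided by `log K`
exceeds the cutoff (normalizing by `log K` makes one cutoff comparable
across model sizes).

### Smoothing, floors, and what the trace records

Three numerical guards shape the M-step:

- **Discrete pseudocount** (default 0.1 per symbol, configurable per
  distribution): weighted counts get an additive pseudocount before
  normalization. This prevents a cluster that never saw a symbol from
  assigning it probability zero — which would veto that symbol forever via
  a −∞ log factor.
- **Variance floor** (1e-6): fitted Gaussian standard deviations are
  clamped from below so a component shrinking onto a single point cannot
  collapse the likelihood to +∞.
- **Component hold**: a component whose responsibility mass falls below
  1e-10·N keeps its previous parameters for that iteration (with a warning)
  instead of dividing by ≈0.

The pseudocount makes the discrete update a Dirichlet-MAP step, so the
quantity EM provably ascends is not the raw data log likelihood but the
penalized objective *loglik + Σ α·log θ* (the smoothing prior term, zero
when smoothing is off). The `EMTrace` records exactly this objective;
convergence is declared when its absolute change drops below `loglik_tol`,
never on the first iteration (there is nothing to compare against). The
variance floor is a constrained M-step and needs no correction term: the
constrained maximizer still satisfies the EM inequality.

### Initialization and restarts

Two seeded strategies:

- `posterior` (default): responsibilities drawn from a flat Dirichlet per
  row, then one M-step.
- `seed_rows`: each component is fitted around one randomly chosen sample
  (weight 1 on the seed plus a uniform background weight of 0.5 spread over
  all rows). This exists because component fits that pool many rows —
  dependence trees in particular — average the Dirichlet row noise away,
  leaving all components nearly identical and EM stalled at the symmetric
  fixed point. Anchoring components on actual samples breaks the symmetry
  reliably (planted-topology recovery went from 7/10 to 10/10 seeds in our
  tree benchmark).

`rand_max_em` runs EM from `n_restarts` initializations (restart r seeded
as `(seed, r)`) and keeps the run with the best final objective.

### Missing values

One sentinel per dataset (`?` for tables; gap characters for sequences),
encoded as NaN internally. A missing entry contributes a log-factor of 0 to
any density and is excluded from every weighted-fit sum — the standard
exact marginalization for independent features. In dependence trees a
conditional factor enters only when child *and* parent are observed; this
drops slightly more information than exact marginalization over the tree
but keeps fitting closed-form.

### Feature ranking

Features are ranked by a responsibility-weighted symmetrized
Kullback–Leibler divergence between per-component marginals:
`scoreⱼ = Σ_{k<l} w_k w_l [KL(θₖⱼ‖θₗⱼ) + KL(θₗⱼ‖θₖⱼ)]` with `w_k` the
component's responsibility share. Closed forms are used for all three
distribution types; CSI-shared parameters contribute zero by construction.

## CSI mixtures and structural EM

A `CSIStructure` stores, per feature, a partition of the K components into
blocks with one parameter set per block. Densities resolve through the
structure, so an all-singleton structure is exactly the conventional
mixture (this identity is tested to 1e-12) and a one-block-per-feature
structure is a single naive-Bayes model.

Structure search is greedy and bottom-up per feature: starting from
singletons, repeatedly merge the pair of blocks whose merge most improves
the score, until no merge improves it. The score of a feature partition is
the responsibility-weighted expected complete-data log likelihood of
block-refit distributions minus `penalty_weight · #free parameters`, with
`penalty_weight = ½·log N` by default (the BIC coefficient; configurable).
Two deliberate choices here:

- Scoring refits use **exact MLE** (no pseudocount; the variance floor
  stays). With MLE refits, a merge can never out-score the corresponding
  split at zero penalty — each block's own maximizer dominates the pooled
  parameters — so the penalty is the only force toward parsimony, which is
  the intended semantics. The M-step parameters themselves keep the usual
  smoothing.
- Ties break toward the merge involving the lowest component index, making
  the search deterministic given responsibilities.

Structure moves begin only after a burn-in of plain parameter EM. The
default burn-in is adaptive: structural search starts once the EM objective
improvement falls below 10·`loglik_tol` (capped at half of `max_iter`). A
premature merge identifies two components' parameters at a feature and can
never be undone by later EM, so merging while responsibilities are still
diffuse irreversibly fuses clusters; with a short fixed burn-in the planted
structure in our benchmark was recovered in 1 of 20 seeds, with the
adaptive burn-in plus 5-restart selection in 20 of 20. A fixed integer
burn-in remains available. A candidate structure replaces the current one
only when it scores strictly higher under the current responsibilities.

Because the penalty intentionally trades likelihood for parsimony, a
structure change may lower the likelihood; the monotone-trace guarantee
applies to EM under a fixed structure (which is a constrained M-step).
Components whose block membership coincides at every feature are merged by
`merge_redundant_components` — π summed, K reduced, every row density
unchanged (tested to 1e-12).

## Dependence trees

A `DTreeComponent` factorizes the joint as a root marginal times one
conditional per non-root feature. Conditionals are conditional Gaussians
(child mean linear in the parent: intercept, slope, residual stdev ≥ floor)
or per-parent-symbol probability tables with pseudocount smoothing. The
conditional-Gaussian tree has `3p − 1` free parameters — linear in p, like
a diagonal-covariance Gaussian, while capturing first-order dependence.

Topology is estimated by the Chow–Liu construction: the maximum-weight
spanning tree of the pairwise mutual-information graph, computed by Kruskal
with edges inserted in lexicographic order so that stable sorting breaks
weight ties toward the lexicographically smallest optimal edge set
(determinism). MI is the plug-in estimate from weighted joint frequencies
for discrete pairs and the Gaussian closed form `−½·log(1−ρ²)` on the
weighted correlation for continuous pairs — matching the
conditional-Gaussian model class, for which this choice makes the MI tree
exactly the maximum-likelihood tree. Constant features get an all-zero MI
row (warning) and end up as leaves. Mixed discrete/continuous edges are not
supported; the tree family requires a homogeneous dataset.

The root is presentation-only — the joint is invariant to re-rooting a
fixed undirected topology when conditionals are refit (tested to 1e-9) —
and defaults to feature 0. In a mixture, each component's tree is refit
from its responsibility-weighted data at every M-step, so topologies differ
per component and per iteration; components can optionally freeze their
topology (`frozen=True`) for stability late in a run.

### Identifiability caveat for planted tree mixtures

A two-cluster discrete instance whose clusters differ only through which
symbols they use is *not* a valid recovery benchmark: a single tree whose
conditional tables depend on the parent symbol represents that two-cluster
joint almost exactly (we measured a log-likelihood gap of ≈2 units at
n=4000), so the mixture split sits on a flat ridge and EM cannot (and need
not) find the planted partition. The recovery benchmarks therefore plant
conditional-Gaussian trees with separated means: a single unimodal Gaussian
tree cannot absorb a bimodal marginal, which makes the plant identifiable.

## Semi-supervised estimation

Pairwise knowledge enters as symmetric matrices `w⁺, w⁻ ∈ [0,1]^{N×N}`
(zero diagonal). The constrained E-step tilts each sample's posterior by
the expected violation penalty against its partners' responsibilities:

```
r_ik ∝ πₖ P(xᵢ|θₖ) · exp(−λ⁺ Σⱼ w⁺ᵢⱼ (1−rⱼₖ)) · exp(−λ⁻ Σⱼ w⁻ᵢⱼ rⱼₖ)
```

Constrained rows are updated in a deterministic sequential sweep (index
order, each row seeing the freshest values). A simultaneous update of all
rows oscillates with period 2 under strong positive coupling — the same
behaviour as synchronous dynamics in an attractive pairwise field — and
never reaches the co-assignment fixed point; the sequential sweep converges
to it. With empty constraints or zero penalties the step reduces exactly to
the unconstrained E-step. The reported objective is
`loglik − λ⁺·E[positive violations] − λ⁻·E[negative violations]` (expected
violations under the current responsibilities, each unordered pair counted
once); convergence is tested on this objective, since the raw likelihood
need not be monotone under constraints. Mixture weights are re-estimated
from the constrained responsibilities like any M-step. Penalties are not
normalized by the number of constrained neighbours.

Hard labels clamp the labelled rows' responsibilities to indicators —
the exact λ→∞ limit — with everything else unchanged; with every sample
labelled, one M-step yields the per-class supervised MLE.
`labels_to_constraints` converts labels to the equivalent binary constraint
set.

**Practical guidance measured on synthetic data:** positive-only
constraints with a large penalty are hazardous when clusters overlap,
because the penalized objective can always be improved by co-assigning
everything to a single component; we observed EM collapsing the partition
(mean ARI drop 0.1–0.2) in exactly the configuration "only positive pairs,
λ large, overlapping clusters" — with every update scheme we tried,
including an exact joint E-step over constraint connected components, so it
is a property of the objective rather than of the approximation. With
correct positive *and* negative pairs and a moderate penalty (λ⁺ = λ⁻ = 2,
10+10 pairs on n=120, cluster means ±0.8σ) the constrained fit strictly
improved the adjusted Rand index in 16 of 20 seeds (mean gain ≈ +0.08);
this balanced regime is what the tests and the acceptance script measure.

## Synthetic data and what the tests show

The sampler draws a component per row from π, then features from that
component (products directly; CSI through the structure; trees in
topological order), bit-reproducibly for a fixed seed. All benchmarks run
on such data with known generators, e.g.:

- Gaussian recovery: π=(0.4,0.6), means ±3, σ=1, n=1000, 5 restarts —
  means within 0.2 and weights within 0.05 up to permutation.
- CSI recovery: K=5, p=4, block means separated by 4σ, n=2000; the planted
  per-feature partitions include partial sharing, full sharing, and full
  distinctness.
- Tree recovery: chain vs star conditional-Gaussian clusters at means ±3,
  slope 0.9, n=4000.

Synthetic draws are i.i.d. and exactly follow the model class being
fitted. Real biological data are not: features carry outliers and
heavier-than-Gaussian tails, missingness can be informative,
sequence positions are not independent given the cluster, and the true
number of clusters is unknown. Passing these benchmarks shows the
estimators are correct and stable under their own assumptions; it does not
certify performance under model misspecification.

## Problem sizes

Test and acceptance problem sizes (n between 120 and 4000, p ≤ 10, K ≤ 5,
up to 50 seeded EM runs and 20-seed recovery trials) were chosen so each
property is measured with comfortable statistical margin while the whole
suite stays quick to run on a laptop; all of them are configurable at the
API level.

## Known limitations

- Continuous features are Gaussian or exponential only; no full-covariance
  components, no Dirichlet priors beyond pseudocount smoothing.
- Dependence trees require homogeneous feature types, and their
  missing-data handling drops factors rather than marginalizing exactly.
- Model selection over K is delegated to CSI merging; there is no
  information-criterion sweep over K.
- The constrained E-step is a mean-field approximation; exact inference
  over constraint cliques is not implemented.
- Sequences must be pre-aligned (fixed length); no alignment is performed.
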