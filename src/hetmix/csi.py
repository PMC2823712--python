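"""Context-specific independence (CSI) mixtures and structural EM.

A CSI mixture relaxes the one-parameter-set-per-(component, feature) layout
of a naive-Bayes mixture: for each feature the K components are partitioned
into parameter-sharing blocks, and all components in a block use one common
distribution for that feature.  The all-singleton structure is exactly the
conventional mixture; a single block per feature is a single naive-Bayes
model.  Components that end up in the same block at *every* feature are
indistinguishable and can be merged, so structure learning doubles as an
automatic reduction of K.

Structure is learned inside EM (structural EM): after the responsibilities
stabilize, each feature's partition is re-selected by greedy bottom-up block
merging under a penalized expected complete-data log-likelihood score,

    score(partition_j) = Σ_B  ll_B  −  penalty_weight · #free_params(B)

where ll_B is the responsibility-weighted log likelihood of feature j under
a block-refit maximum-likelihood distribution with block weights
w_i = Σ_{k∈B} r_ik.  The default penalty weight ½·log N gives a BIC-style
trade-off.  Scoring uses exact (unsmoothed) MLE refits so that with a zero
penalty a merge can never beat the split it replaces; the M-step parameters
themselves are fitted with the usual smoothing defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DataSet
from .distributions import (DegenerateFitError, DiscreteDistribution,
                            ProductComponent)
from .mixture import EMSettings, EMTrace, MixtureModel, e_step, m_step

__all__ = [
    "CSIStructure",
    "CSIMixtureModel",
    "csi_log_density",
    "score_structure",
    "structural_em",
    "merge_redundant_components",
]


class CSIStructure:
    """Per-feature partition of components into parameter-sharing blocks.

    ``blocks[j]`` is a list of sorted component-index tuples partitioning
    {0..K−1}; ``dists[j]`` holds one distribution per block, aligned."""

    def __init__(self, blocks: Sequence[Sequence[tuple[int, ...]]],
                 dists: Sequence[Sequence]):
        self.blocks = [[tuple(sorted(b)) for b in feat] for feat in blocks]
        self.dists = [list(feat) for feat in dists]
        if len(self.blocks) != len(self.dists):
            raise ValueError("blocks/dists feature count mismatch")
        K = sum(len(b) for b in self.blocks[0])
        for j, (fb, fd) in enumerate(zip(self.blocks, self.dists)):
            if len(fb) != len(fd):
                raise ValueError(f"feature {j}: block/dist count mismatch")
            if any(len(b) == 0 for b in fb):
                raise ValueError(f"feature {j}: empty block")
            covered = sorted(k for b in fb for k in b)
            if covered != list(range(K)):
                raise ValueError(
                    f"feature {j}: blocks must partition components 0..{K - 1}")
        self.K = K

    @property
    def p(self) -> int:
        return len(self.blocks)

    def block_index_of(self, j: int, k: int) -> int:
        for b, block in enumerate(self.blocks[j]):
            if k in block:
                return b
        raise KeyError((j, k))

    def dist_of(self, j: int, k: int):
        return self.dists[j][self.block_index_of(j, k)]

    def signature(self, k: int) -> tuple[int, ...]:
        """Block index of component k at every feature (merge key)."""
        return tuple(self.block_index_of(j, k) for j in range(self.p))

    def n_parameters(self) -> int:
        return sum(d.n_parameters for feat in self.dists for d in feat)

    def is_all_singleton(self) -> bool:
        return all(len(fb) == self.K for fb in self.blocks)

    def render(self) -> str:
        """Text rendering of the component×feature sharing matrix: cells with
        the same letter in a column share one parameter set."""
        letters = "abcdefghijklmnopqrstuvwxyz"
        lines = ["component\t" + "\t".join(f"X{j}" for j in range(self.p))]
        for k in range(self.K):
            cells = [letters[self.block_index_of(j, k) % 26]
                     for j in range(self.p)]
            lines.append(f"C{k}\t" + "\t".join(cells))
        return "\n".join(lines)


class CSIMixtureModel(MixtureModel):
    """Mixture whose component densities are resolved through a CSI structure."""

    def __init__(self, pi, structure: CSIStructure):
        self.structure = structure
        components = [_CSIComponentView(structure, k)
                      for k in range(structure.K)]
        super().__init__(pi, components)

    @classmethod
    def from_mixture(cls, model: MixtureModel) -> "CSIMixtureModel":
        """All-singleton CSI wrap of a conventional naive-Bayes mixture."""
        K, p = model.K, model.p
        blocks = [[(k,) for k in range(K)] for _ in range(p)]
        dists = [[model.components[k].feature_dists[j] for k in range(K)]
                 for j in range(p)]
        return cls(model.pi.copy(), CSIStructure(blocks, dists))

    @property
    def p(self) -> int:
        return self.structure.p

    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        out = np.zeros((n, self.K))
        for j in range(self.p):
            for block, dist in zip(self.structure.blocks[j],
                                   self.structure.dists[j]):
                ld = dist.log_density_codes(X[:, j])
                for k in block:
                    out[:, k] += ld
        return out

    def log_prior(self) -> float:
        return sum(d.log_prior()
                   for feat in self.structure.dists for d in feat)

    def with_updated(self, pi, components) -> "CSIMixtureModel":
        # components are views; the refit happened on the structure in
        # fit_components, which returns the new structure via views
        structure = components[0].structure
        return CSIMixtureModel(pi, structure)

    def fit_components(self, dataset: DataSet,
                       responsibilities: np.ndarray) -> list:
        new_dists = []
        for j in range(self.p):
            feat = []
            for block, dist in zip(self.structure.blocks[j],
                                   self.structure.dists[j]):
                w = responsibilities[:, list(block)].sum(axis=1)
                try:
                    feat.append(dist.fit_weighted(dataset.X[:, j], w))
                except DegenerateFitError:
                    feat.append(dist)
            new_dists.append(feat)
        structure = CSIStructure(self.structure.blocks, new_dists)
        return [_CSIComponentView(structure, k) for k in range(self.K)]

    def with_structure(self, structure: CSIStructure) -> "CSIMixtureModel":
        return CSIMixtureModel(self.pi.copy(), structure)

    def expand(self) -> MixtureModel:
        """Equivalent conventional mixture (shared parameters copied)."""
        comps = []
        for k in range(self.K):
            comps.append(ProductComponent(
                [self.structure.dist_of(j, k) for j in range(self.p)]))
        return MixtureModel(self.pi.copy(), comps)

    def feature_domains(self):
        from .mixture import _domains_from_dists
        return _domains_from_dists(
            [self.structure.dist_of(j, 0) for j in range(self.p)])

    def feature_marginals(self) -> list[list]:
        return [[self.structure.dist_of(j, k) for k in range(self.K)]
                for j in range(self.p)]

    def sample_component_rows(self, k, rng, size):
        cols = [self.structure.dist_of(j, k).sample_codes(rng, size)
                for j in range(self.p)]
        return np.column_stack(cols)

    def n_parameters(self) -> int:
        return (self.K - 1) + self.structure.n_parameters()


class _CSIComponentView:
    """Component k as seen through the structure (density delegate)."""

    def __init__(self, structure: CSIStructure, k: int):
        self.structure = structure
        self.k = k

    @property
    def p(self) -> int:
        return self.structure.p

    @property
    def n_parameters(self) -> int:  # shared params counted at model level
        return sum(self.structure.dist_of(j, self.k).n_parameters
                   for j in range(self.p))

    @property
    def feature_dists(self):
        return [self.structure.dist_of(j, self.k) for j in range(self.p)]

    def log_density_rows(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0])
        for j in range(self.p):
            out += self.structure.dist_of(j, self.k).log_density_codes(X[:, j])
        return out

    def log_prior(self) -> float:
        return 0.0  # accounted once per block on the model

    def sample_rows(self, rng, size):
        cols = [self.structure.dist_of(j, self.k).sample_codes(rng, size)
                for j in range(self.p)]
        return np.column_stack(cols)


def csi_log_density(model: CSIMixtureModel, row, k: int,
                    encoded: bool = False) -> float:
    """Log density of one row under component k, shared parameters resolved
    through the structure."""
    if k >= model.K:
        raise ValueError(f"component {k} out of range (K={model.K})")
    if not encoded:
        from .data import _encode_row
        row = _encode_row(row, model.feature_domains(), "?")
    row = np.asarray(row, dtype=float)
    return float(model.components[k].log_density_rows(row[None, :])[0])


# ---------------------------------------------------------------------------
# structure scoring and search

def _mle_refit(dist, values: np.ndarray, weights: np.ndarray):
    """Exact-MLE refit used for scoring (no pseudocount; stdev floor kept)."""
    if isinstance(dist, DiscreteDistribution):
        return dist.fit_weighted(values, weights, pseudocount=0.0)
    return dist.fit_weighted(values, weights)


def _block_score(dist, values: np.ndarray, weights: np.ndarray,
                 penalty_weight: float) -> float:
    """Weighted log likelihood of a block under its MLE refit, minus the
    parameter penalty.  Zero-weight values contribute nothing."""
    try:
        fitted = _mle_refit(dist, values, weights)
    except DegenerateFitError:
        fitted = dist
    ld = fitted.log_density_codes(values)
    mask = weights > 0
    ll = float(np.dot(weights[mask], np.where(np.isfinite(ld[mask]),
                                              ld[mask], 0.0)))
    # exact-MLE zeros only occur at zero-weight observations, handled above
    if np.any(~np.isfinite(ld[mask])):
        ll = -math.inf
    return ll - penalty_weight * fitted.n_parameters


def score_structure(structure: CSIStructure, dataset: DataSet,
                    responsibilities: np.ndarray,
                    penalty_weight: float | None = None) -> float:
    """Penalized expected complete-data log likelihood of a structure.

    Higher is better; deterministic in its inputs.  ``penalty_weight``
    defaults to ½·log N (BIC-style)."""
    if penalty_weight is None:
        penalty_weight = 0.5 * math.log(dataset.n)
    total = 0.0
    for j in range(structure.p):
        values = dataset.X[:, j]
        for block, dist in zip(structure.blocks[j], structure.dists[j]):
            if not block:
                raise ValueError(f"feature {j}: empty block")
            w = responsibilities[:, list(block)].sum(axis=1)
            total += _block_score(dist, values, w, penalty_weight)
    return total


def _greedy_feature_partition(values: np.ndarray, dist_template,
                              responsibilities: np.ndarray,
                              penalty_weight: float
                              ) -> list[tuple[int, ...]]:
    """Bottom-up agglomerative block merging for one feature.

    Starts from singletons; repeatedly merges the block pair with the best
    score improvement until none improves.  Ties break toward the pair whose
    (smallest, second-smallest) leading component indices come first."""
    K = responsibilities.shape[1]
    blocks = [(k,) for k in range(K)]

    def score_of(block: tuple[int, ...]) -> float:
        w = responsibilities[:, list(block)].sum(axis=1)
        return _block_score(dist_template, values, w, penalty_weight)

    scores = {b: score_of(b) for b in blocks}
    while len(blocks) > 1:
        best = None
        for a_i in range(len(blocks)):
            for b_i in range(a_i + 1, len(blocks)):
                a, b = blocks[a_i], blocks[b_i]
                merged = tuple(sorted(a + b))
                if merged not in scores:
                    scores[merged] = score_of(merged)
                delta = scores[merged] - scores[a] - scores[b]
                key = (-delta, merged)
                if delta > 1e-12 and (best is None or key < best[0]):
                    best = (key, a_i, b_i, merged)
        if best is None:
            break
        _, a_i, b_i, merged = best
        blocks = ([b for i, b in enumerate(blocks) if i not in (a_i, b_i)]
                  + [merged])
        blocks.sort()
    return sorted(blocks)


def learn_structure(model: CSIMixtureModel, dataset: DataSet,
                    responsibilities: np.ndarray,
                    penalty_weight: float | None = None) -> CSIStructure:
    """Greedy per-feature structure selection given fixed responsibilities."""
    if penalty_weight is None:
        penalty_weight = 0.5 * math.log(dataset.n)
    blocks, dists = [], []
    for j in range(model.p):
        template = model.structure.dists[j][0]
        part = _greedy_feature_partition(dataset.X[:, j], template,
                                         responsibilities, penalty_weight)
        feat_dists = []
        for block in part:
            w = responsibilities[:, list(block)].sum(axis=1)
            try:
                feat_dists.append(template.fit_weighted(dataset.X[:, j], w))
            except DegenerateFitError:
                feat_dists.append(template)
        blocks.append(part)
        dists.append(feat_dists)
    return CSIStructure(blocks, dists)


def structural_em(model: CSIMixtureModel, dataset: DataSet,
                  settings: EMSettings,
                  penalty_weight: float | None = None,
                  burn_in: int | str = "auto", search_interval: int = 1
                  ) -> tuple[CSIMixtureModel, EMTrace]:
    """EM interleaved with per-feature structure selection.

    The first ``burn_in`` iterations run plain parameter EM so the
    responsibilities stabilize before any structural move; a premature merge
    identifies component parameters and cannot be undone, so the default
    ``"auto"`` burns in until the EM objective improvement falls below
    10·loglik_tol (capped at half of max_iter).  Afterwards the structure is
    re-selected every ``search_interval``-th iteration and adopted only when
    its penalized score beats the current structure's.  Convergence is
    tested on the EM objective; iterations where the structure changes never
    trigger it."""
    if penalty_weight is None:
        penalty_weight = 0.5 * math.log(dataset.n)
    adaptive = burn_in == "auto"
    burn_cap = settings.max_iter // 2 if adaptive else int(burn_in)
    burned_in = False
    trace = EMTrace()
    prev = None
    for it in range(1, settings.max_iter + 1):
        resp, loglik = e_step(model, dataset)
        obj = loglik + model.log_prior()
        trace.loglik_per_iter.append(obj)
        trace.n_iter = it
        structure_changed = False
        if not burned_in:
            if adaptive:
                burned_in = (it > burn_cap
                             or (prev is not None
                                 and abs(obj - prev) < 10 * settings.loglik_tol))
            else:
                burned_in = it > burn_cap
            search_due = burned_in
        else:
            search_due = (it % search_interval) == 0
        if search_due:
            candidate = learn_structure(model, dataset, resp, penalty_weight)
            if candidate.blocks != model.structure.blocks:
                cur_score = score_structure(model.structure, dataset, resp,
                                            penalty_weight)
                new_score = score_structure(candidate, dataset, resp,
                                            penalty_weight)
                if new_score > cur_score + 1e-12:
                    model = model.with_structure(candidate)
                    structure_changed = True
        if (prev is not None and not structure_changed
                and abs(obj - prev) < settings.loglik_tol):
            trace.converged = True
            break
        prev = obj
        model = m_step(model, dataset, resp)
    return model, trace


def rand_max_structural_em(model: CSIMixtureModel, dataset: DataSet,
                           settings: EMSettings,
                           penalty_weight: float | None = None,
                           burn_in: int | str = "auto",
                           search_interval: int = 1
                           ) -> tuple[CSIMixtureModel, EMTrace]:
    """Structural EM from ``settings.n_restarts`` random-posterior starts;
    keeps the run with the best final objective (local-optimum hedge, like
    plain EM restarts)."""
    from .mixture import random_init
    best = None
    for r in range(settings.n_restarts):
        rng = np.random.default_rng([settings.seed, r])
        init = random_init(model, dataset, rng)
        fitted, trace = structural_em(init, dataset, settings,
                                      penalty_weight=penalty_weight,
                                      burn_in=burn_in,
                                      search_interval=search_interval)
        if best is None or trace.final_loglik > best[1].final_loglik:
            best = (fitted, trace)
    return best


def merge_redundant_components(model: CSIMixtureModel) -> CSIMixtureModel:
    """Collapse components that share the same block at every feature.

    Their mixture weights are summed and K decreases; the mixture density of
    every row is unchanged."""
    seen: dict[tuple[int, ...], int] = {}
    keep: list[int] = []
    merged_pi: list[float] = []
    for k in range(model.K):
        sig = model.structure.signature(k)
        if sig in seen:
            merged_pi[seen[sig]] += model.pi[k]
        else:
            seen[sig] = len(keep)
            keep.append(k)
            merged_pi.append(float(model.pi[k]))
    if len(keep) == model.K:
        return model
    remap = {old: new for new, old in enumerate(keep)}
    blocks, dists = [], []
    for j in range(model.p):
        fb, fd = [], []
        for block, dist in zip(model.structure.blocks[j],
                               model.structure.dists[j]):
            nb = tuple(sorted(remap[k] for k in block if k in remap))
            if nb:
                fb.append(nb)
                fd.append(dist)
        order = sorted(range(len(fb)), key=lambda i: fb[i])
        blocks.append([fb[i] for i in order])
        dists.append([fd[i] for i in order])
    pi = np.asarray(merged_pi)
    return CSIMixtureModel(pi / pi.sum(), CSIStructure(blocks, dists))
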