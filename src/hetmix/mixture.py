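"""Finite mixture models and EM estimation.

The model is the K-component mixture density

    P(x | Θ) = Σ_k π_k · P(x | θ_k)

with naive-Bayes product components by default (subclasses provide CSI and
dependence-tree components).  Estimation is by expectation–maximization:
the E-step computes the component-membership posterior (responsibility)

    P(k | x_i, Θ) = π_k P(x_i|θ_k) / Σ_m π_m P(x_i|θ_m)

and the M-step re-fits π and each component by responsibility-weighted
maximum likelihood.  Because discrete fits use pseudocount smoothing (a
Dirichlet-MAP update), the iteration provably ascends the *penalized* log
likelihood — data log likelihood plus the smoothing prior term — and that
is the objective the :class:`EMTrace` records; with smoothing disabled it
coincides with the data log likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .data import ClusterAssignment, DataSet, FeatureDomain
from .distributions import DiscreteDistribution, kl_divergence

__all__ = [
    "MixtureModel",
    "EMSettings",
    "EMTrace",
    "DegeneracyError",
    "mixture_log_density",
    "e_step",
    "m_step",
    "em",
    "random_init",
    "rand_max_em",
    "classify",
    "rank_features",
]

#: a component whose total responsibility falls below COLLAPSE_FLOOR·N has
#: its parameters frozen for the iteration instead of dividing by ~0
COLLAPSE_FLOOR = 1e-10


class DegeneracyError(RuntimeError):
    """Numeric degeneracy during EM (e.g. a sample with zero likelihood
    under every component)."""


@dataclass
class EMSettings:
    """Knobs for a single EM run and for restart strategies."""

    max_iter: int = 100
    loglik_tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 1
    entropy_cutoff: float | None = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        if not self.loglik_tol > 0:
            raise ValueError("loglik_tol must be positive")


@dataclass
class EMTrace:
    """Per-iteration objective values of one EM run."""

    loglik_per_iter: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def final_loglik(self) -> float:
        return self.loglik_per_iter[-1]


class MixtureModel:
    """Mixture weights π plus K components exposing ``log_density_rows``,
    ``fit_weighted``, ``sample_rows``, ``log_prior`` and ``n_parameters``."""

    def __init__(self, pi, components: Sequence):
        pi = np.asarray(pi, dtype=float)
        if pi.ndim != 1 or len(components) != pi.shape[0] or pi.shape[0] < 1:
            raise ValueError("pi and components must align, K ≥ 1")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be nonnegative and sum to 1")
        self.pi = pi
        self.components = list(components)

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def p(self) -> int:
        return self.components[0].p

    def __repr__(self):
        return f"{type(self).__name__}(K={self.K}, p={self.p})"

    # -- densities ----------------------------------------------------------
    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """N×K matrix of log P(x_i | θ_k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [c.log_density_rows(X) for c in self.components])

    def log_density_rows(self, X: np.ndarray) -> np.ndarray:
        logs = self.component_log_densities(X)
        with np.errstate(divide="ignore"):
            return logsumexp(logs + np.log(self.pi), axis=1)

    def log_prior(self) -> float:
        """Smoothing-prior term of the EM objective (0 without smoothing)."""
        return sum(c.log_prior() for c in self.components)

    # -- structure-aware hooks (overridden by CSI subclass) -----------------
    def with_updated(self, pi, components) -> "MixtureModel":
        return type(self)(pi, components)

    def fit_components(self, dataset: DataSet,
                       responsibilities: np.ndarray) -> list:
        n = dataset.n
        new = []
        for k, comp in enumerate(self.components):
            w = responsibilities[:, k]
            if w.sum() < COLLAPSE_FLOOR * n:
                warnings.warn(
                    f"component {k} collapsed (responsibility mass "
                    f"{w.sum():.3g}); holding its parameters", RuntimeWarning)
                new.append(comp)
            else:
                new.append(comp.fit_weighted(dataset.X, w))
        return new

    # -- sampling -----------------------------------------------------------
    def sample_component_rows(self, k: int, rng: np.random.Generator,
                              size: int) -> np.ndarray:
        return self.components[k].sample_rows(rng, size)

    def feature_domains(self) -> list[FeatureDomain]:
        dists = self.components[0].feature_dists
        return _domains_from_dists(dists)

    def n_parameters(self) -> int:
        return (self.K - 1) + sum(c.n_parameters for c in self.components)

    def feature_marginals(self) -> list[list]:
        """marginals[j][k] = distribution of feature j under component k."""
        return [[self.components[k].feature_dists[j] for k in range(self.K)]
                for j in range(self.p)]


def _domains_from_dists(dists) -> list[FeatureDomain]:
    out = []
    for j, d in enumerate(dists):
        if isinstance(d, DiscreteDistribution):
            out.append(FeatureDomain("discrete", d.alphabet, name=f"f{j}"))
        else:
            out.append(FeatureDomain("continuous", name=f"f{j}"))
    return out


# ---------------------------------------------------------------------------
# EM machinery

def mixture_log_density(model: MixtureModel, row,
                        encoded: bool = False) -> float:
    """log Σ_k π_k P(row | θ_k) for a single observation vector.

    ``row`` holds raw values (symbols/numbers, missing marker "?") unless
    ``encoded=True``."""
    if not encoded:
        domains = model.feature_domains()
        from .data import _encode_row
        row = _encode_row(row, domains, "?")
    return float(model.log_density_rows(np.asarray(row, float)[None, :])[0])


def e_step(model: MixtureModel, dataset: DataSet
           ) -> tuple[np.ndarray, float]:
    """Responsibilities P(k|x_i,Θ) and the total data log likelihood."""
    logs = model.component_log_densities(dataset.X)
    with np.errstate(divide="ignore"):
        joint = logs + np.log(model.pi)
    norm = logsumexp(joint, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        ids = [dataset.ids[i] for i in np.flatnonzero(bad)[:5]]
        raise DegeneracyError(
            f"zero likelihood under every component for sample(s) {ids}")
    resp = np.exp(joint - norm[:, None])
    return resp, float(norm.sum())


def m_step(model: MixtureModel, dataset: DataSet,
           responsibilities: np.ndarray) -> MixtureModel:
    """Weighted-MLE update of π and all component parameters."""
    resp = np.asarray(responsibilities, dtype=float)
    if resp.shape != (dataset.n, model.K):
        raise ValueError("responsibility matrix shape mismatch")
    pi = resp.sum(axis=0) / dataset.n
    pi = pi / pi.sum()
    components = model.fit_components(dataset, resp)
    return model.with_updated(pi, components)


def em(model: MixtureModel, dataset: DataSet, settings: EMSettings,
       callback: Callable[[int, float], None] | None = None
       ) -> tuple[MixtureModel, EMTrace]:
    """Alternate E- and M-steps until the objective improves by less than
    ``loglik_tol`` or ``max_iter`` is reached.

    The first iteration never triggers convergence (there is no previous
    objective to compare against)."""
    trace = EMTrace()
    prev = None
    for it in range(1, settings.max_iter + 1):
        try:
            resp, loglik = e_step(model, dataset)
        except DegeneracyError as err:
            raise DegeneracyError(f"iteration {it}: {err}") from err
        obj = loglik + model.log_prior()
        trace.loglik_per_iter.append(obj)
        trace.n_iter = it
        if callback is not None:
            callback(it, obj)
        if prev is not None and abs(obj - prev) < settings.loglik_tol:
            trace.converged = True
            break
        prev = obj
        model = m_step(model, dataset, resp)
    return model, trace


def random_init(model: MixtureModel, dataset: DataSet,
                rng: np.random.Generator,
                strategy: str = "posterior") -> MixtureModel:
    """Random initialization ahead of EM.

    ``"posterior"`` draws responsibilities from a flat Dirichlet per row and
    applies one M-step.  ``"seed_rows"`` instead anchors each component on
    one randomly chosen sample (weight 1 on the seed, a small uniform
    background weight on everything else) — useful when component fits
    average row-level Dirichlet noise away and EM stalls at the symmetric
    solution, as happens with dependence-tree components."""
    if strategy == "posterior":
        resp = rng.dirichlet(np.ones(model.K), size=dataset.n)
        return m_step(model, dataset, resp)
    if strategy == "seed_rows":
        seeds = rng.choice(dataset.n, size=model.K, replace=False)
        background = 0.5 / dataset.n
        components = []
        for k, comp in enumerate(model.components):
            w = np.full(dataset.n, background)
            w[seeds[k]] += 1.0
            components.append(comp.fit_weighted(dataset.X, w))
        return model.with_updated(np.full(model.K, 1.0 / model.K),
                                  components)
    raise ValueError(f"unknown init strategy {strategy!r}")


def rand_max_em(model: MixtureModel, dataset: DataSet, settings: EMSettings,
                init_strategy: str = "posterior"
                ) -> tuple[MixtureModel, EMTrace]:
    """Run EM from ``n_restarts`` random initializations; keep the best run.

    Restart r uses the deterministic seed sequence (settings.seed, r)."""
    if settings.n_restarts < 1:
        raise ValueError("n_restarts must be ≥ 1")
    best: tuple[MixtureModel, EMTrace] | None = None
    errors = []
    for r in range(settings.n_restarts):
        rng = np.random.default_rng([settings.seed, r])
        try:
            init = random_init(model, dataset, rng, strategy=init_strategy)
            fitted, trace = em(init, dataset, settings)
        except DegeneracyError as err:
            errors.append(f"restart {r}: {err}")
            continue
        if best is None or trace.final_loglik > best[1].final_loglik:
            best = (fitted, trace)
    if best is None:
        raise DegeneracyError(
            "all EM restarts degenerated: " + "; ".join(errors))
    return best


def classify(model: MixtureModel, dataset: DataSet,
             entropy_cutoff: float | None = None) -> ClusterAssignment:
    """Argmax cluster assignment with an optional entropy gate.

    A sample whose posterior entropy, normalized by log K, exceeds
    ``entropy_cutoff`` is left unassigned (label −1).  Ties break toward
    the lowest component index."""
    resp, _ = e_step(model, dataset)
    labels = np.argmax(resp, axis=1)
    if entropy_cutoff is not None and model.K > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(resp > 0, resp * np.log(resp), 0.0).sum(axis=1)
        ent /= np.log(model.K)
        labels = np.where(ent > entropy_cutoff, -1, labels)
    return ClusterAssignment(labels, resp)


def rank_features(model: MixtureModel, dataset: DataSet
                  ) -> list[tuple[int, float]]:
    """Rank features by how strongly they separate the components.

    The score of feature j is the responsibility-weighted symmetrized KL
    divergence between the per-component marginals of that feature,

        score_j = Σ_{k<l} w_k w_l · [KL(θ_kj‖θ_lj) + KL(θ_lj‖θ_kj)]

    with w_k the fraction of responsibility mass on component k.  Returns
    (feature index, score) pairs sorted by descending score, ties broken by
    feature index."""
    if model.K < 2:
        raise ValueError("feature ranking needs K ≥ 2")
    resp, _ = e_step(model, dataset)
    w = resp.sum(axis=0) / dataset.n
    marginals = model.feature_marginals()
    scores = []
    for j in range(model.p):
        s = 0.0
        for k in range(model.K):
            for l in range(k + 1, model.K):
                dk, dl = marginals[j][k], marginals[j][l]
                if dk is dl:
                    continue  # shared CSI parameterization: zero divergence
                s += w[k] * w[l] * (kl_divergence(dk, dl) + kl_divergence(dl, dk))
        scores.append(s)
    order = sorted(range(model.p), key=lambda j: (-scores[j], j))
    return [(j, scores[j]) for j in order]
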