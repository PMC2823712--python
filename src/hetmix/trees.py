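"""Dependence-tree component distributions and their mixture EM.

A dependence tree relaxes naive-Bayes independence to first-order
dependencies: given a directed tree over the p features with parent map
``pa``, the joint density factorizes as

    P(x) = P(x_root) · Π_{j ≠ root} P(x_j | x_{pa(j)})

with conditional Gaussians (child mean linear in the parent) for continuous
features and conditional probability tables for discrete ones.  The
maximum-likelihood topology is the classic Chow-Liu construction: a
maximum-weight spanning tree of the pairwise mutual-information graph.
When dependence trees serve as mixture components, each component's
topology is re-estimated from its responsibility-weighted data at every EM
iteration, so clusters may carry different dependency structures.

Only homogeneous trees (all-discrete or all-continuous datasets) are
supported; mixed parent/child edges raise an error.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import networkx as nx
import numpy as np

from .data import DataSet, FeatureDomain
from .distributions import (DegenerateFitError, DiscreteDistribution,
                            GaussianDistribution, STDEV_FLOOR)
from .mixture import EMSettings, EMTrace, MixtureModel, em

__all__ = [
    "TreeTopology",
    "ConditionalGaussian",
    "ConditionalDiscrete",
    "DTreeComponent",
    "dtree_log_density",
    "mutual_information_matrix",
    "max_weight_spanning_tree",
    "fit_dtree",
    "em_dtree_mixture",
]

_LOG_2PI = math.log(2.0 * math.pi)


class TreeTopology:
    """Directed tree over features: parent map (−1 at the root) plus root."""

    def __init__(self, parent: Sequence[int], root: int):
        parent = np.asarray(parent, dtype=int)
        p = parent.shape[0]
        if p < 1:
            raise ValueError("topology needs at least one feature")
        if not (0 <= root < p) or parent[root] != -1:
            raise ValueError("root must be the unique parentless feature")
        if np.sum(parent == -1) != 1:
            raise ValueError("exactly one root allowed")
        # acyclicity / spanning check by walking to the root
        for j in range(p):
            seen, cur = set(), j
            while cur != -1:
                if cur in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(cur)
                cur = parent[cur]
        self.parent = parent
        self.root = int(root)

    @property
    def p(self) -> int:
        return self.parent.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs."""
        return [(int(self.parent[j]), j) for j in range(self.p)
                if j != self.root]

    def undirected_edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges()}

    def topological_order(self) -> list[int]:
        order, children = [self.root], {}
        for pa, ch in self.edges():
            children.setdefault(pa, []).append(ch)
        i = 0
        while i < len(order):
            order.extend(sorted(children.get(order[i], [])))
            i += 1
        return order

    def to_newick(self) -> str:
        children = {}
        for pa, ch in self.edges():
            children.setdefault(pa, []).append(ch)

        def rec(j):
            kids = sorted(children.get(j, []))
            if not kids:
                return f"X{j}"
            return "(" + ",".join(rec(c) for c in kids) + f")X{j}"

        return rec(self.root) + ";"


class ConditionalGaussian:
    """Child | parent Gaussian: mean = intercept + slope·parent value."""

    kind = "continuous"

    def __init__(self, intercept: float, slope: float, noise_stdev: float):
        if not noise_stdev > 0:
            raise ValueError("noise_stdev must be positive")
        self.intercept = float(intercept)
        self.slope = float(slope)
        self.noise_stdev = float(noise_stdev)

    @property
    def n_parameters(self) -> int:
        return 3

    def log_density_pairs(self, child: np.ndarray, parent: np.ndarray
                          ) -> np.ndarray:
        z = (child - self.intercept - self.slope * parent) / self.noise_stdev
        return -0.5 * (z * z + _LOG_2PI) - math.log(self.noise_stdev)

    def sample_given(self, parent: np.ndarray, rng) -> np.ndarray:
        mean = self.intercept + self.slope * parent
        return rng.normal(mean, self.noise_stdev)

    def log_prior(self) -> float:
        return 0.0

    def to_dict(self) -> dict:
        return {"type": "cond_gaussian", "intercept": self.intercept,
                "slope": self.slope, "noise_stdev": self.noise_stdev}


class ConditionalDiscrete:
    """Child | parent probability table: one child pmf row per parent symbol."""

    kind = "discrete"

    def __init__(self, parent_alphabet: Sequence[str],
                 child_alphabet: Sequence[str], table,
                 pseudocount: float = 0.1):
        table = np.asarray(table, dtype=float)
        if table.shape != (len(parent_alphabet), len(child_alphabet)):
            raise ValueError("table shape must be |parent| × |child|")
        if np.any(table < 0) or np.any(np.abs(table.sum(axis=1) - 1) > 1e-12):
            raise ValueError("each table row must be a probability vector")
        self.parent_alphabet = tuple(parent_alphabet)
        self.child_alphabet = tuple(child_alphabet)
        self.table = table
        self.pseudocount = float(pseudocount)

    @property
    def n_parameters(self) -> int:
        return len(self.parent_alphabet) * (len(self.child_alphabet) - 1)

    def log_density_pairs(self, child: np.ndarray, parent: np.ndarray
                          ) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logt = np.log(self.table)
        return logt[parent.astype(int), child.astype(int)]

    def sample_given(self, parent: np.ndarray, rng) -> np.ndarray:
        out = np.empty(parent.shape[0])
        for s in range(len(self.parent_alphabet)):
            idx = np.flatnonzero(parent.astype(int) == s)
            if idx.size:
                out[idx] = rng.choice(len(self.child_alphabet), size=idx.size,
                                      p=self.table[s])
        return out

    def log_prior(self) -> float:
        if self.pseudocount == 0:
            return 0.0
        pos = self.table[self.table > 0]
        return float(self.pseudocount * np.log(pos).sum())

    def to_dict(self) -> dict:
        return {"type": "cond_discrete",
                "parent_alphabet": list(self.parent_alphabet),
                "child_alphabet": list(self.child_alphabet),
                "table": self.table.tolist(),
                "pseudocount": self.pseudocount}


class DTreeComponent:
    """Tree-factorized joint: root marginal plus per-edge conditionals."""

    def __init__(self, topology: TreeTopology, root_dist,
                 edge_dists: dict[int, object], frozen: bool = False):
        if set(edge_dists) != {j for j in range(topology.p)
                               if j != topology.root}:
            raise ValueError("need exactly one conditional per non-root feature")
        self.topology = topology
        self.root_dist = root_dist
        self.edge_dists = dict(edge_dists)
        #: when True, fit_weighted refits parameters on the fixed topology
        self.frozen = frozen

    @property
    def p(self) -> int:
        return self.topology.p

    @property
    def n_parameters(self) -> int:
        return self.root_dist.n_parameters + sum(
            d.n_parameters for d in self.edge_dists.values())

    def log_density_rows(self, X: np.ndarray) -> np.ndarray:
        """Row log densities; a factor enters only when its child (and for
        edges, its parent) is observed."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"row arity {X.shape[1]} != tree arity {self.p}")
        out = self.root_dist.log_density_codes(X[:, self.topology.root])
        for pa, ch in self.topology.edges():
            both = ~np.isnan(X[:, ch]) & ~np.isnan(X[:, pa])
            if np.any(both):
                out[both] += self.edge_dists[ch].log_density_pairs(
                    X[both, ch], X[both, pa])
        return out

    def fit_weighted(self, X: np.ndarray, weights) -> "DTreeComponent":
        dataset = _array_dataset(X, self._domains())
        fitted = fit_dtree(dataset, weights, root=self.topology.root,
                           topology=self.topology if self.frozen else None)
        fitted.frozen = self.frozen
        return fitted

    def sample_rows(self, rng, size: int) -> np.ndarray:
        X = np.empty((size, self.p))
        X[:, self.topology.root] = self.root_dist.sample_codes(rng, size)
        for j in self.topology.topological_order()[1:]:
            X[:, j] = self.edge_dists[j].sample_given(
                X[:, self.topology.parent[j]], rng)
        return X

    def log_prior(self) -> float:
        return self.root_dist.log_prior() + sum(
            d.log_prior() for d in self.edge_dists.values())

    def _domains(self) -> list[FeatureDomain]:
        doms = []
        for j in range(self.p):
            if isinstance(self.root_dist, DiscreteDistribution):
                if j == self.topology.root:
                    alpha = self.root_dist.alphabet
                else:
                    alpha = self.edge_dists[j].child_alphabet
                doms.append(FeatureDomain("discrete", alpha, name=f"f{j}"))
            else:
                doms.append(FeatureDomain("continuous", name=f"f{j}"))
        return doms

    @property
    def feature_dists(self):
        raise TypeError("dependence-tree components have no per-feature "
                        "marginals; feature ranking is undefined for them")

    def to_dict(self) -> dict:
        return {"type": "dtree",
                "parent": self.topology.parent.tolist(),
                "root": self.topology.root,
                "root_dist": self.root_dist.to_dict(),
                "edge_dists": {str(j): d.to_dict()
                               for j, d in sorted(self.edge_dists.items())}}


def _array_dataset(X: np.ndarray, domains) -> DataSet:
    X = np.asarray(X, dtype=float)
    return DataSet([f"r{i}" for i in range(X.shape[0])], X, domains)


def dtree_log_density(component: DTreeComponent, row,
                      encoded: bool = False) -> float:
    """Joint log density of one row under the tree factorization."""
    if not encoded:
        from .data import _encode_row
        row = _encode_row(row, component._domains(), "?")
    row = np.asarray(row, dtype=float)
    return float(component.log_density_rows(row[None, :])[0])


# ---------------------------------------------------------------------------
# structure estimation

def mutual_information_matrix(dataset: DataSet, weights) -> np.ndarray:
    """Weighted pairwise mutual information (nats), p×p symmetric, zero
    diagonal.

    Discrete pairs use the plug-in estimate from weighted joint frequencies;
    continuous pairs use the Gaussian closed form −½·log(1−ρ²) on the
    weighted correlation.  A constant feature gets an all-zero row (with a
    warning)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    kinds = {d.kind for d in dataset.domains}
    if len(kinds) > 1:
        raise ValueError("mixed discrete/continuous trees are not supported")
    p = dataset.p
    M = np.zeros((p, p))
    constant = [_is_constant(dataset, j, w) for j in range(p)]
    for a in range(p):
        if constant[a]:
            warnings.warn(f"feature {a} is constant; MI row zeroed",
                          RuntimeWarning)
            continue
        for b in range(a + 1, p):
            if constant[b]:
                continue
            M[a, b] = M[b, a] = _pairwise_mi(dataset, a, b, w)
    return M


def _is_constant(dataset: DataSet, j: int, w: np.ndarray) -> bool:
    col = dataset.X[:, j]
    mask = ~np.isnan(col) & (w > 0)
    vals = col[mask]
    return vals.size == 0 or np.all(vals == vals[0])


def _pairwise_mi(dataset: DataSet, a: int, b: int, w: np.ndarray) -> float:
    xa, xb = dataset.X[:, a], dataset.X[:, b]
    both = ~np.isnan(xa) & ~np.isnan(xb)
    xa, xb, ww = xa[both], xb[both], w[both]
    total = ww.sum()
    if total <= 0:
        return 0.0
    if dataset.domains[a].kind == "discrete":
        na = len(dataset.domains[a].alphabet)
        nb = len(dataset.domains[b].alphabet)
        joint = np.zeros((na, nb))
        np.add.at(joint, (xa.astype(int), xb.astype(int)), ww)
        joint /= total
        pa_ = joint.sum(axis=1, keepdims=True)
        pb_ = joint.sum(axis=0, keepdims=True)
        mask = joint > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log(joint / (pa_ @ pb_))
        return float(np.sum(joint[mask] * ratio[mask]))
    ma = np.dot(ww, xa) / total
    mb = np.dot(ww, xb) / total
    va = np.dot(ww, (xa - ma) ** 2) / total
    vb = np.dot(ww, (xb - mb) ** 2) / total
    if va <= 0 or vb <= 0:
        return 0.0
    rho = np.dot(ww, (xa - ma) * (xb - mb)) / total / math.sqrt(va * vb)
    rho = min(max(rho, -1 + 1e-12), 1 - 1e-12)
    return float(-0.5 * math.log1p(-rho * rho))


def max_weight_spanning_tree(weight_matrix: np.ndarray,
                             root: int = 0) -> TreeTopology:
    """Maximum-weight spanning tree, directed away from ``root``.

    Ties are deterministic: edges enter Kruskal in lexicographic order and
    the stable sort keeps that order among equal weights, so the
    lexicographically smallest optimal edge set is returned."""
    W = np.asarray(weight_matrix, dtype=float)
    p = W.shape[0]
    if p == 0:
        raise ValueError("empty weight matrix")
    if W.shape != (p, p) or not np.allclose(W, W.T):
        raise ValueError("weight matrix must be square and symmetric")
    if not (0 <= root < p):
        raise ValueError("root out of range")
    if p == 1:
        return TreeTopology([-1], 0)
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for a in range(p):
        for b in range(a + 1, p):
            G.add_edge(a, b, weight=float(W[a, b]))
    T = nx.maximum_spanning_tree(G, algorithm="kruskal")
    parent = np.full(p, -1, dtype=int)
    for u, v in nx.bfs_edges(T, root):
        parent[v] = u
    return TreeTopology(parent, root)


def fit_dtree(dataset: DataSet, weights, root: int = 0,
              pseudocount: float = 0.1,
              stdev_floor: float = STDEV_FLOOR,
              topology: TreeTopology | None = None) -> DTreeComponent:
    """Chow-Liu fit: MI matrix → maximum-weight spanning tree → weighted-MLE
    root marginal and per-edge conditionals.

    Pass ``topology`` to skip structure estimation and refit parameters on a
    fixed tree (used e.g. when freezing topologies late in EM)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise DegenerateFitError("dtree fit with zero total weight")
    if topology is not None:
        topo = topology
    else:
        M = mutual_information_matrix(dataset, w)
        topo = max_weight_spanning_tree(M, root=root)
    discrete = dataset.domains[0].kind == "discrete"
    rj = topo.root
    if discrete:
        alpha = dataset.domains[rj].alphabet
        template = DiscreteDistribution(alpha, np.full(len(alpha),
                                                       1 / len(alpha)),
                                        pseudocount=pseudocount)
        root_dist = template.fit_weighted(dataset.X[:, rj], w)
    else:
        root_dist = GaussianDistribution(0.0, 1.0).fit_weighted(
            dataset.X[:, rj], w, stdev_floor=stdev_floor)
    edge_dists: dict[int, object] = {}
    for pa, ch in topo.edges():
        if discrete:
            edge_dists[ch] = _fit_cond_discrete(
                dataset, pa, ch, w, pseudocount)
        else:
            edge_dists[ch] = _fit_cond_gaussian(dataset, pa, ch, w,
                                                stdev_floor)
    return DTreeComponent(topo, root_dist, edge_dists)


def _fit_cond_discrete(dataset, pa, ch, w, pseudocount) -> ConditionalDiscrete:
    ap = dataset.domains[pa].alphabet
    ac = dataset.domains[ch].alphabet
    xp, xc = dataset.X[:, pa], dataset.X[:, ch]
    both = ~np.isnan(xp) & ~np.isnan(xc)
    counts = np.zeros((len(ap), len(ac)))
    np.add.at(counts, (xp[both].astype(int), xc[both].astype(int)), w[both])
    counts += pseudocount if pseudocount > 0 else 0.0
    rowsum = counts.sum(axis=1, keepdims=True)
    uniform = np.full(len(ac), 1 / len(ac))
    table = np.where(rowsum > 0, counts / np.where(rowsum > 0, rowsum, 1.0),
                     uniform)
    return ConditionalDiscrete(ap, ac, table, pseudocount=pseudocount)


def _fit_cond_gaussian(dataset, pa, ch, w, stdev_floor) -> ConditionalGaussian:
    xp, xc = dataset.X[:, pa], dataset.X[:, ch]
    both = ~np.isnan(xp) & ~np.isnan(xc)
    xp, xc, ww = xp[both], xc[both], w[both]
    total = ww.sum()
    if total <= 0:
        raise DegenerateFitError(f"edge ({pa}→{ch}): zero effective weight")
    mp = np.dot(ww, xp) / total
    mc = np.dot(ww, xc) / total
    vp = np.dot(ww, (xp - mp) ** 2) / total
    cov = np.dot(ww, (xp - mp) * (xc - mc)) / total
    slope = 0.0 if vp <= 0 else cov / vp
    intercept = mc - slope * mp
    resid = xc - intercept - slope * xp
    var = np.dot(ww, resid ** 2) / total
    return ConditionalGaussian(intercept, slope,
                               max(math.sqrt(max(var, 0.0)), stdev_floor))


# ---------------------------------------------------------------------------
# mixture of dependence trees

class DTreeMixtureModel(MixtureModel):
    """Mixture whose components are dependence trees; the M-step re-runs the
    Chow-Liu construction per component, so topologies are re-estimated from
    the responsibility-weighted data at every iteration."""

    def __init__(self, pi, components: Sequence[DTreeComponent]):
        super().__init__(pi, components)

    def feature_domains(self) -> list[FeatureDomain]:
        return self.components[0]._domains()

    def fit_components(self, dataset, responsibilities):
        n = dataset.n
        new = []
        for k, comp in enumerate(self.components):
            w = responsibilities[:, k]
            if w.sum() < 1e-10 * n:
                warnings.warn(f"tree component {k} collapsed; holding "
                              "parameters", RuntimeWarning)
                new.append(comp)
            else:
                new.append(comp.fit_weighted(dataset.X, w))
        return new


def em_dtree_mixture(model: MixtureModel, dataset: DataSet,
                     settings: EMSettings) -> tuple[MixtureModel, EMTrace]:
    """EM for a mixture of dependence trees (per-component Chow-Liu M-step)."""
    return em(model, dataset, settings)
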