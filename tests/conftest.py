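"""Shared builders for random models across all mixture families."""

import numpy as np
import pytest

from hetmix import (CSIMixtureModel, CSIStructure, DiscreteDistribution,
                    DTreeComponent, DTreeMixtureModel, ExponentialDistribution,
                    GaussianDistribution, MixtureModel, ProductComponent,
                    TreeTopology)
from hetmix.trees import ConditionalDiscrete, ConditionalGaussian

DNA = tuple("ACGT")


def random_discrete(rng, alphabet=DNA, conc=1.0):
    return DiscreteDistribution(alphabet, rng.dirichlet(np.full(len(alphabet),
                                                                conc)))


def random_gaussian(rng, spread=3.0):
    return GaussianDistribution(rng.normal(0, spread), rng.uniform(0.5, 2.0))


def random_exponential(rng):
    return ExponentialDistribution(rng.uniform(0.3, 3.0))


def random_pi(rng, K):
    pi = rng.dirichlet(np.full(K, 5.0))
    return pi / pi.sum()


def random_product_mixture(rng, K=2, p=3, kind="gaussian"):
    """Random naive-Bayes mixture; kind in gaussian|discrete|exponential|mixed."""
    makers = {"gaussian": random_gaussian, "discrete": random_discrete,
              "exponential": random_exponential}
    comps = []
    for _ in range(K):
        dists = []
        for j in range(p):
            if kind == "mixed":
                maker = [random_gaussian, random_discrete,
                         random_exponential][j % 3]
            else:
                maker = makers[kind]
            dists.append(maker(rng))
        comps.append(ProductComponent(dists))
    return MixtureModel(random_pi(rng, K), comps)


def random_partition(rng, K):
    """Random partition of {0..K-1} into blocks."""
    labels = rng.integers(0, K, size=K)
    blocks = {}
    for k, lab in enumerate(labels):
        blocks.setdefault(lab, []).append(k)
    return sorted(tuple(b) for b in blocks.values())


def random_csi_mixture(rng, K=3, p=3, kind="gaussian"):
    maker = {"gaussian": random_gaussian, "discrete": random_discrete}[kind]
    blocks, dists = [], []
    for _ in range(p):
        part = random_partition(rng, K)
        blocks.append(part)
        dists.append([maker(rng) for _ in part])
    return CSIMixtureModel(random_pi(rng, K), CSIStructure(blocks, dists))


def random_topology(rng, p):
    """Random labelled tree via a random Prüfer-like parent attachment."""
    order = rng.permutation(p)
    parent = np.full(p, -1, dtype=int)
    for i in range(1, p):
        parent[order[i]] = order[rng.integers(0, i)]
    return TreeTopology(parent, int(order[0]))


def random_dtree_component(rng, p=3, kind="discrete", alphabet=DNA):
    topo = random_topology(rng, p)
    if kind == "discrete":
        root = random_discrete(rng, alphabet)
        edges = {ch: ConditionalDiscrete(
            alphabet, alphabet,
            rng.dirichlet(np.ones(len(alphabet)), size=len(alphabet)))
            for _, ch in topo.edges()}
    else:
        root = random_gaussian(rng)
        edges = {ch: ConditionalGaussian(rng.normal(0, 1),
                                         rng.uniform(-1, 1),
                                         rng.uniform(0.4, 1.5))
                 for _, ch in topo.edges()}
    return DTreeComponent(topo, root, edges)


def random_dtree_mixture(rng, K=2, p=3, kind="discrete"):
    comps = [random_dtree_component(rng, p, kind) for _ in range(K)]
    return DTreeMixtureModel(random_pi(rng, K), comps)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
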