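"""Dependence trees: factorization, MI weights, Chow-Liu, tree-mixture EM."""

import itertools
import math

import numpy as np
import pytest

from hetmix import (DataSet, DiscreteDistribution, DTreeComponent,
                    DTreeMixtureModel, EMSettings, FeatureDomain,
                    GaussianDistribution, TreeTopology, dtree_log_density,
                    em_dtree_mixture, fit_dtree, max_weight_spanning_tree,
                    mutual_information_matrix, random_init, sample_dataset)
from hetmix.trees import ConditionalDiscrete, ConditionalGaussian

from conftest import (DNA, random_dtree_component, random_dtree_mixture,
                      random_topology)


# -- brute-force oracles ----------------------------------------------------

def all_spanning_trees(p):
    """All labelled spanning trees on p nodes, as frozensets of edges."""
    all_edges = list(itertools.combinations(range(p), 2))
    trees = []
    for subset in itertools.combinations(all_edges, p - 1):
        adj = {i: [] for i in range(p)}
        for a, b in subset:
            adj[a].append(b)
            adj[b].append(a)
        seen, stack = {0}, [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) == p:
            trees.append(frozenset(frozenset(e) for e in subset))
    return trees


def tree_weight(edges, W):
    return sum(W[tuple(sorted(e))] for e in edges)


def topology_from_edges(edges, p, root=0):
    adj = {i: [] for i in range(p)}
    for e in edges:
        a, b = sorted(e)
        adj[a].append(b)
        adj[b].append(a)
    parent = np.full(p, -1, dtype=int)
    seen, stack = {root}, [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                stack.append(v)
    return TreeTopology(parent, root)


def planted_gaussian_tree(shape: str, mu: float, slope: float = 0.9,
                          noise: float = 0.6) -> DTreeComponent:
    """Conditional-Gaussian tree cluster: 'chain' 0→1→2→3 or 'star' on 1."""
    if shape == "chain":
        topo = TreeTopology([-1, 0, 1, 2], 0)
    else:
        topo = TreeTopology([1, -1, 1, 1], 1)
    edges = {ch: ConditionalGaussian(mu * (1 - slope), slope, noise)
             for _, ch in topo.edges()}
    return DTreeComponent(topo, GaussianDistribution(mu, 1.0), edges)


def chain_component(tables, root_probs):
    """Discrete tree with the example shape: A→B, B→C, B→D."""
    topo = TreeTopology([-1, 0, 1, 1], 0)
    root = DiscreteDistribution(DNA, root_probs)
    edges = {j: ConditionalDiscrete(DNA, DNA, t)
             for j, t in zip((1, 2, 3), tables)}
    return DTreeComponent(topo, root, edges)


@pytest.fixture
def example_tree(rng):
    tables = [rng.dirichlet(np.ones(4), size=4) for _ in range(3)]
    return chain_component(tables, rng.dirichlet(np.ones(4)))


class TestTopology:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            TreeTopology([1, 0, -1], 2)

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError):
            TreeTopology([-1, -1, 0], 0)

    def test_newick_export(self):
        topo = TreeTopology([-1, 0, 1, 1], 0)
        assert topo.to_newick() == "((X2,X3)X1)X0;"


class TestDTreeDensity:
    def test_factorization_term_by_term(self, example_tree):
        # P(a,b,c,d) = P(a)·P(b|a)·P(c|b)·P(d|b)
        comp = example_tree
        row = np.array([0.0, 2.0, 1.0, 3.0])
        expected = (comp.root_dist.log_density_codes(row[[0]])[0]
                    + math.log(comp.edge_dists[1].table[0, 2])
                    + math.log(comp.edge_dists[2].table[2, 1])
                    + math.log(comp.edge_dists[3].table[2, 3]))
        got = comp.log_density_rows(row[None, :])[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_p1_equals_root_marginal(self, rng):
        root = DiscreteDistribution(DNA, rng.dirichlet(np.ones(4)))
        comp = DTreeComponent(TreeTopology([-1], 0), root, {})
        assert comp.log_density_rows(np.array([[2.0]]))[0] == pytest.approx(
            root.log_density_codes(np.array([2.0]))[0], abs=1e-12)

    def test_parent_ignoring_conditionals_reduce_to_naive_bayes(self, rng):
        # identical table rows == independence of parent
        marg = rng.dirichlet(np.ones(4))
        table = np.tile(marg, (4, 1))
        comp = chain_component([table] * 3, rng.dirichlet(np.ones(4)))
        row = np.array([1.0, 0.0, 3.0, 2.0])
        expected = (comp.root_dist.log_density_codes(row[[0]])[0]
                    + 3 * 0)  # placeholder
        naive = comp.root_dist.log_density_codes(row[[0]])[0] + sum(
            math.log(marg[int(row[j])]) for j in (1, 2, 3))
        assert comp.log_density_rows(row[None, :])[0] == pytest.approx(
            naive, abs=1e-12)

    def test_density_normalizes_over_support(self, rng):
        comp = random_dtree_component(rng, p=4, kind="discrete")
        total = 0.0
        for combo in itertools.product(range(4), repeat=4):
            total += math.exp(comp.log_density_rows(
                np.array(combo, float)[None, :])[0])
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_root_invariance_of_joint(self, rng):
        # refitting conditionals after re-rooting leaves the joint unchanged
        comp = random_dtree_component(rng, p=4, kind="discrete")
        ds, _ = sample_dataset(
            DTreeMixtureModel([1.0], [comp]), 3000, seed=1)
        w = np.ones(ds.n)
        undirected = comp.topology.undirected_edges()
        fits = []
        for root in range(4):
            topo = topology_from_edges(undirected, 4, root=root)
            fits.append(fit_dtree(ds, w, topology=topo, pseudocount=0.0))
        X = ds.X[:50]
        base = fits[0].log_density_rows(X)
        for f in fits[1:]:
            np.testing.assert_allclose(f.log_density_rows(X), base,
                                       atol=1e-9)

    def test_conditional_gaussian_parameter_count_linear_in_p(self, rng):
        p = 6
        comp = random_dtree_component(rng, p=p, kind="continuous")
        # root: mean+stdev, each of p−1 edges: intercept+slope+noise
        assert comp.n_parameters == 2 + 3 * (p - 1) == 3 * p - 1
        assert len(comp.topology.edges()) == p - 1


class TestMutualInformation:
    def test_independent_features_near_zero(self, rng):
        model = DTreeMixtureModel([1.0], [random_dtree_component(
            rng, p=1, kind="discrete")])
        # build an independent 3-feature discrete dataset directly
        X = rng.integers(0, 4, size=(10 ** 4, 3)).astype(float)
        doms = [FeatureDomain("discrete", DNA) for _ in range(3)]
        ds = DataSet([f"s{i}" for i in range(10 ** 4)], X, doms)
        M = mutual_information_matrix(ds, np.ones(10 ** 4))
        off = M[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.01)  # plug-in bias ~ (|A|−1)²/2n

    def test_duplicated_feature_gives_entropy(self, rng):
        x = rng.integers(0, 4, size=2000).astype(float)
        doms = [FeatureDomain("discrete", DNA)] * 2
        ds = DataSet([f"s{i}" for i in range(2000)], np.column_stack([x, x]),
                     doms)
        M = mutual_information_matrix(ds, np.ones(2000))
        freqs = np.bincount(x.astype(int), minlength=4) / 2000
        H = -np.sum(freqs[freqs > 0] * np.log(freqs[freqs > 0]))
        assert M[0, 1] == pytest.approx(H, abs=1e-12)

    def test_bivariate_gaussian_closed_form(self):
        rng = np.random.default_rng(11)
        n = 200_000
        x = rng.normal(size=n)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=n)
        doms = [FeatureDomain("continuous")] * 2
        ds = DataSet([f"s{i}" for i in range(n)], np.column_stack([x, y]),
                     doms)
        M = mutual_information_matrix(ds, np.ones(n))
        assert M[0, 1] == pytest.approx(-0.5 * math.log(0.75), abs=0.01)

    def test_constant_feature_zeroed_with_warning(self):
        X = np.column_stack([np.zeros(100), np.arange(100, dtype=float)])
        doms = [FeatureDomain("continuous")] * 2
        ds = DataSet([f"s{i}" for i in range(100)], X, doms)
        with pytest.warns(RuntimeWarning, match="constant"):
            M = mutual_information_matrix(ds, np.ones(100))
        assert np.all(M == 0)


class TestMaxWeightSpanningTree:
    def test_p2_single_edge(self):
        topo = max_weight_spanning_tree(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert topo.root == 0
        assert topo.edges() == [(0, 1)]

    def test_star_example_topology(self):
        # weights AB:3, BC:2, BD:2, AC:1, AD:1, CD:1 → {AB, BC, BD}
        W = np.zeros((4, 4))
        for (a, b), w in {(0, 1): 3, (1, 2): 2, (1, 3): 2, (0, 2): 1,
                          (0, 3): 1, (2, 3): 1}.items():
            W[a, b] = W[b, a] = w
        topo = max_weight_spanning_tree(W, root=0)
        assert topo.undirected_edges() == {frozenset(e) for e in
                                           [(0, 1), (1, 2), (1, 3)]}

    @pytest.mark.parametrize("p", [3, 4, 5])
    def test_matches_exhaustive_enumeration(self, p):
        rng = np.random.default_rng(p)
        for _ in range(10):
            W = rng.uniform(0, 1, size=(p, p))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            topo = max_weight_spanning_tree(W)
            got = sum(W[pa, ch] for pa, ch in topo.edges())
            best = max(tree_weight(t, W) for t in all_spanning_trees(p))
            assert got == pytest.approx(best, abs=1e-12)


class TestFitDTree:
    def test_recovers_planted_chain(self, rng):
        # X1→X2→X3 with strong dependence
        t_strong = np.full((4, 4), 0.1 / 3) + np.eye(4) * (0.9 - 0.1 / 3)
        t_strong /= t_strong.sum(axis=1, keepdims=True)
        topo = TreeTopology([-1, 0, 1], 0)
        comp = DTreeComponent(topo, DiscreteDistribution(DNA, [0.25] * 4),
                              {1: ConditionalDiscrete(DNA, DNA, t_strong),
                               2: ConditionalDiscrete(DNA, DNA, t_strong)})
        ds, _ = sample_dataset(DTreeMixtureModel([1.0], [comp]), 5000, seed=2)
        fit = fit_dtree(ds, np.ones(5000))
        assert fit.topology.undirected_edges() == topo.undirected_edges()

    def test_independent_features_fit_marginal_like_conditionals(self, rng):
        X = rng.integers(0, 4, size=(5000, 3)).astype(float)
        doms = [FeatureDomain("discrete", DNA)] * 3
        ds = DataSet([f"s{i}" for i in range(5000)], X, doms)
        fit = fit_dtree(ds, np.ones(5000))
        for cond in fit.edge_dists.values():
            spread = cond.table.max(axis=0) - cond.table.min(axis=0)
            assert np.all(spread < 0.1)

    def test_chow_liu_optimality_against_all_trees(self):
        # fitted tree's weighted loglik beats every alternative topology
        # refit the same way (exact-MLE fits, p=4 brute force)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            comp = random_dtree_component(rng, p=4, kind="discrete")
            ds, _ = sample_dataset(DTreeMixtureModel([1.0], [comp]), 1000,
                                   seed=seed)
            w = np.ones(ds.n)
            best = fit_dtree(ds, w, pseudocount=0.0)
            ll_best = float(best.log_density_rows(ds.X).sum())
            for edges in all_spanning_trees(4):
                topo = topology_from_edges(edges, 4)
                alt = fit_dtree(ds, w, topology=topo, pseudocount=0.0)
                ll_alt = float(alt.log_density_rows(ds.X).sum())
                assert ll_best >= ll_alt - 1e-9


class TestDTreeMixtureEM:
    def test_k1_reduces_to_single_chow_liu_fit(self, rng):
        comp = random_dtree_component(rng, p=3, kind="discrete")
        model = DTreeMixtureModel([1.0], [comp])
        ds, _ = sample_dataset(model, 800, seed=3)
        fitted, _ = em_dtree_mixture(model, ds,
                                     EMSettings(max_iter=2, loglik_tol=1e-9))
        direct = fit_dtree(ds, np.ones(800))
        assert fitted.components[0].topology.undirected_edges() == \
            direct.topology.undirected_edges()

    def test_recovers_two_planted_topologies(self):
        # chain vs star conditional-Gaussian clusters, mean-separated so a
        # single tree cannot absorb both (bimodality forces a real split)
        from hetmix import rand_max_em

        true = DTreeMixtureModel(
            [0.5, 0.5],
            [planted_gaussian_tree("chain", -3.0),
             planted_gaussian_tree("star", 3.0)])
        ds, labels = sample_dataset(true, 4000, seed=4)
        fitted, _ = rand_max_em(
            true, ds,
            EMSettings(max_iter=80, loglik_tol=1e-6, seed=4, n_restarts=5),
            init_strategy="seed_rows")
        got = {frozenset(map(tuple, c.topology.undirected_edges()))
               for c in fitted.components}
        want = {frozenset(map(tuple, c.topology.undirected_edges()))
                for c in true.components}
        assert got == want

    def test_loglik_trace_nondecreasing_over_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            kind = "discrete" if seed % 2 == 0 else "continuous"
            model = random_dtree_mixture(rng, K=2, p=3, kind=kind)
            ds, _ = sample_dataset(model, 300, seed=seed)
            init = random_init(model, ds, rng)
            _, trace = em_dtree_mixture(
                init, ds, EMSettings(max_iter=15, loglik_tol=1e-9))
            diffs = np.diff(trace.loglik_per_iter)
            assert np.all(diffs >= -1e-8), f"seed {seed}: {diffs.min()}"
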