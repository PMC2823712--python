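"""Cluster fixed-length DNA sequences from a FASTA file.

Builds a two-cluster positional model (one cluster A-rich, one G-rich),
simulates 40 sequences of length 10 to a FASTA file, reads them back (each
position becomes one discrete feature), clusters with EM restarts, and
prints cluster sizes plus the positions ranked by how strongly they
separate the clusters."""

import tempfile
from pathlib import Path

import numpy as np

from hetmix import (DiscreteDistribution, EMSettings, MixtureModel,
                    ProductComponent, classify, rand_max_em, rank_features,
                    read_fasta, sample_dataset, write_fasta)

DNA = tuple("ACGT")


def positional_component(bias_symbol, informative):
    """Uniform positions except the informative ones, biased to one base."""
    dists = []
    for pos in range(10):
        p = np.full(4, 0.25)
        if pos in informative:
            p = np.full(4, 0.05)
            p[DNA.index(bias_symbol)] = 0.85
        dists.append(DiscreteDistribution(DNA, p))
    return ProductComponent(dists)


true = MixtureModel([0.5, 0.5], [
    positional_component("A", informative={2, 3, 4}),
    positional_component("G", informative={2, 3, 4})])

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "sequences.fa"
    data, labels = sample_dataset(true, 40, seed=7)
    write_fasta(data, fasta)
    data = read_fasta(fasta)          # N=40 sequences → p=10 features

fitted, trace = rand_max_em(
    true, data, EMSettings(max_iter=40, loglik_tol=0.1, seed=1,
                           n_restarts=5))
for i, ll in enumerate(trace.loglik_per_iter, 1):
    print(f"Step {i}: log likelihood: {ll:.4f}")

assignment = classify(fitted, data, entropy_cutoff=0.9)
for label, members in assignment.cluster_members(data.ids).items():
    name = "Unassigned (entropy cutoff)" if label < 0 else f"Cluster {label}"
    print(f"{name}, size {len(members)}: {members[:6]}{'…' if len(members) > 6 else ''}")

print("\npositions ranked by cluster relevance (symmetrized KL):")
for j, score in rank_features(fitted, data)[:5]:
    print(f"  position {j}: {score:.3f}")
print("the informative positions 2–4 should rank first; uniform positions "
      "score ≈ 0.")
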