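"""Semi-supervised clustering: partial hard labels and pairwise constraints.

Two heavily overlapping 1-D Gaussian clusters (means ±0.8) are nearly
unidentifiable from data alone.  The example first clusters them
unsupervised, then (a) with 10% hard labels and (b) with ten correct
positive plus ten correct negative pairwise constraints at a moderate
penalty, printing the adjusted Rand index against the generating labels in
each case."""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from hetmix import (ConstraintSet, EMSettings, GaussianDistribution,
                    LabelSet, MixtureModel, PenaltyWeights, ProductComponent,
                    constrained_e_step, constrained_em, e_step, em,
                    labeled_em, random_init, sample_dataset)

true = MixtureModel([0.5, 0.5], [
    ProductComponent([GaussianDistribution(-0.8, 1.0)]),
    ProductComponent([GaussianDistribution(+0.8, 1.0)])])
data, labels = sample_dataset(true, 120, seed=6)
settings = EMSettings(max_iter=60, loglik_tol=1e-7, seed=6)


def ari_of(model, resp=None):
    if resp is None:
        resp, _ = e_step(model, data)
    return adjusted_rand_score(labels, np.argmax(resp, axis=1))


# unsupervised baseline
init = random_init(true, data, np.random.default_rng([6, 0]))
m_unsup, _ = em(init, data, settings)
print(f"unsupervised ARI:          {ari_of(m_unsup):.3f}")

# 10% hard labels: those rows are clamped to indicators during EM
known = LabelSet({i: int(labels[i]) for i in range(0, 120, 10)})
m_lab, _ = labeled_em(true, data, known, settings)
print(f"10% hard labels ARI:       {ari_of(m_lab):.3f}")

# correct positive + negative pairwise constraints, moderate penalties
rng = np.random.default_rng(6)
w_pos, w_neg = np.zeros((120, 120)), np.zeros((120, 120))
p = q = 0
while p < 10:
    i, j = rng.integers(0, 120, size=2)
    if i != j and labels[i] == labels[j] and w_pos[i, j] == 0:
        w_pos[i, j] = w_pos[j, i] = 1.0
        p += 1
while q < 10:
    i, j = rng.integers(0, 120, size=2)
    if i != j and labels[i] != labels[j] and w_neg[i, j] == 0:
        w_neg[i, j] = w_neg[j, i] = 1.0
        q += 1
cons = ConstraintSet(w_pos, w_neg)
pen = PenaltyWeights(lambda_pos=2.0, lambda_neg=2.0)
m_con, _ = constrained_em(true, data, cons, pen, settings)
base, _ = e_step(m_con, data)
resp_con, _ = constrained_e_step(m_con, data, cons, pen, base)
print(f"20 pairwise constraints ARI: {ari_of(m_con, resp_con):.3f}")
print("higher ARI with side information shows the labels/constraints "
      "resolving assignments the overlapping likelihoods cannot.")
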