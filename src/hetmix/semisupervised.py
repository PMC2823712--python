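"""Semi-supervised mixture estimation: hard labels and soft pairwise
constraints.

Prior knowledge enters either as partial hard labels (known component for a
subset of samples) or as soft pairwise constraints: symmetric weights
w⁺_ij, w⁻_ij ∈ [0,1] expressing a preference for samples i and j to share,
respectively not share, a cluster.  Constraint violations are penalized in
the E-step posterior through Lagrange-style penalty weights λ⁺, λ⁻:

    r_ik ∝ π_k P(x_i|θ_k)
           · exp(−λ⁺ Σ_j w⁺_ij (1 − r'_jk))
           · exp(−λ⁻ Σ_j w⁻_ij r'_jk)

where r'_jk are the previous iteration's responsibilities (uniform 1/K at
the first iteration).  With empty constraints or zero penalties this is
exactly the unconstrained posterior.  Hard labels are the binary,
non-overlapping, λ→∞ special case; ``labeled_em`` implements that limit
directly by clamping labelled rows to indicators.

Convergence is monitored on the penalized objective
loglik − λ⁺·(expected positive violations) − λ⁻·(expected negative
violations), since the raw likelihood need not be monotone under
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import DataSet
from .mixture import (DegeneracyError, EMSettings, EMTrace, MixtureModel,
                      m_step, random_init)

__all__ = [
    "ConstraintSet",
    "PenaltyWeights",
    "LabelSet",
    "constrained_e_step",
    "constrained_em",
    "labeled_em",
    "labels_to_constraints",
    "read_constraints",
    "read_labels",
]


class ConstraintSet:
    """Symmetric pairwise positive/negative constraint weights in [0,1]."""

    def __init__(self, w_pos: np.ndarray, w_neg: np.ndarray):
        w_pos = np.asarray(w_pos, dtype=float)
        w_neg = np.asarray(w_neg, dtype=float)
        for name, w in (("w_pos", w_pos), ("w_neg", w_neg)):
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError(f"{name} must be a square matrix")
            if not np.allclose(w, w.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(w) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if w_pos.shape != w_neg.shape:
            raise ValueError("w_pos / w_neg shape mismatch")
        self.w_pos = w_pos
        self.w_neg = w_neg

    @classmethod
    def empty(cls, n: int) -> "ConstraintSet":
        return cls(np.zeros((n, n)), np.zeros((n, n)))

    @property
    def n(self) -> int:
        return self.w_pos.shape[0]

    def is_empty(self) -> bool:
        return not (self.w_pos.any() or self.w_neg.any())


@dataclass(frozen=True)
class PenaltyWeights:
    """Penalty weights λ⁺ (positive violations) and λ⁻ (negative)."""

    lambda_pos: float = 1.0
    lambda_neg: float = 1.0

    def __post_init__(self):
        if self.lambda_pos < 0 or self.lambda_neg < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass
class LabelSet:
    """Partial hard labels: map sample index → component index."""

    labels: dict[int, int] = field(default_factory=dict)

    def validate(self, n: int, k: int) -> None:
        for i, lab in self.labels.items():
            if not (0 <= i < n):
                raise ValueError(f"labelled sample index {i} out of range")
            if not (0 <= lab < k):
                raise ValueError(f"label {lab} out of range for K={k}")


def constrained_e_step(model: MixtureModel, dataset: DataSet,
                       constraints: ConstraintSet, penalties: PenaltyWeights,
                       prev_resp: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """Penalized posterior update; returns (responsibilities, penalized
    objective).

    Each sample's posterior is tilted by the expected constraint-violation
    penalty against its partners' responsibilities.  Constrained rows are
    updated in a sequential sweep (index order, each seeing the freshest
    values), which is the stable mean-field scheme — a simultaneous update
    oscillates with period 2 under strong positive coupling, exactly like
    synchronous dynamics in an attractive pairwise field.  Reduces exactly
    to the unconstrained E-step when the constraints are empty or both
    penalties are zero."""
    if constraints.n != dataset.n:
        raise ValueError("constraint matrix size does not match dataset")
    prev = np.asarray(prev_resp, dtype=float)
    if prev.shape != (dataset.n, model.K):
        raise ValueError("prev_resp shape mismatch")
    logs = model.component_log_densities(dataset.X)
    with np.errstate(divide="ignore"):
        joint = logs + np.log(model.pi)
    loglik = float(logsumexp(joint, axis=1).sum())

    constrained_rows = np.flatnonzero(
        constraints.w_pos.any(axis=1) | constraints.w_neg.any(axis=1))
    # unconstrained rows: plain posterior, computed in one shot
    norm = logsumexp(joint, axis=1)
    if np.any(~np.isfinite(norm)):
        bad = [dataset.ids[i] for i in np.flatnonzero(~np.isfinite(norm))[:5]]
        raise DegeneracyError(f"zero likelihood for sample(s) {bad}")
    resp = np.exp(joint - norm[:, None])
    if constrained_rows.size:
        cur = prev.copy()
        for i in constrained_rows:
            pen = (penalties.lambda_pos
                   * (constraints.w_pos[i] @ (1.0 - cur))
                   + penalties.lambda_neg * (constraints.w_neg[i] @ cur))
            row = joint[i] - pen
            z = logsumexp(row)
            if not np.isfinite(z):
                raise DegeneracyError(
                    f"zero penalized likelihood for sample {dataset.ids[i]}")
            cur[i] = np.exp(row - z)
        resp[constrained_rows] = cur[constrained_rows]
    objective = loglik - _violation_penalty(constraints, penalties, resp)
    return resp, objective


def _violation_penalty(constraints: ConstraintSet, penalties: PenaltyWeights,
                       resp: np.ndarray) -> float:
    """λ⁺·E[positive violations] + λ⁻·E[negative violations] over pairs."""
    co = resp @ resp.T  # co-assignment probability per pair
    pos = 0.5 * float(np.sum(constraints.w_pos * (1.0 - co)))
    neg = 0.5 * float(np.sum(constraints.w_neg * co))
    return penalties.lambda_pos * pos + penalties.lambda_neg * neg


def constrained_em(model: MixtureModel, dataset: DataSet,
                   constraints: ConstraintSet, penalties: PenaltyWeights,
                   settings: EMSettings, init: bool = True
                   ) -> tuple[MixtureModel, EMTrace]:
    """EM with the constrained E-step and the standard M-step.

    ``prev_resp`` is uniform at iteration 0; the trace records the
    penalized objective.  With ``init=True`` the model is first
    random-posterior initialized from ``settings.seed`` (so an empty
    constraint set reproduces the unconstrained run exactly)."""
    if init:
        rng = np.random.default_rng([settings.seed, 0])
        model = random_init(model, dataset, rng)
    trace = EMTrace()
    prev_obj = None
    prev_resp = np.full((dataset.n, model.K), 1.0 / model.K)
    for it in range(1, settings.max_iter + 1):
        resp, objective = constrained_e_step(model, dataset, constraints,
                                             penalties, prev_resp)
        trace.loglik_per_iter.append(objective + model.log_prior())
        trace.n_iter = it
        if prev_obj is not None and abs(trace.loglik_per_iter[-1]
                                        - prev_obj) < settings.loglik_tol:
            trace.converged = True
            break
        prev_obj = trace.loglik_per_iter[-1]
        model = m_step(model, dataset, resp)
        prev_resp = resp
    return model, trace


def labeled_em(model: MixtureModel, dataset: DataSet, labels: LabelSet,
               settings: EMSettings, init: bool = True
               ) -> tuple[MixtureModel, EMTrace]:
    """EM with labelled rows clamped to their label's indicator posterior.

    Unlabelled rows get the ordinary posterior; the M-step is standard.
    With every sample labelled this is supervised per-class estimation
    (one M-step suffices; further iterations are fixed points)."""
    labels.validate(dataset.n, model.K)
    if init:
        rng = np.random.default_rng([settings.seed, 0])
        model = random_init(model, dataset, rng)
    idx = np.array(sorted(labels.labels), dtype=int)
    lab = np.array([labels.labels[i] for i in idx], dtype=int)
    trace = EMTrace()
    prev = None
    from .mixture import e_step
    for it in range(1, settings.max_iter + 1):
        resp, loglik = e_step(model, dataset)
        if idx.size:
            resp[idx] = 0.0
            resp[idx, lab] = 1.0
        obj = loglik + model.log_prior()
        trace.loglik_per_iter.append(obj)
        trace.n_iter = it
        if prev is not None and abs(obj - prev) < settings.loglik_tol:
            trace.converged = True
            break
        prev = obj
        model = m_step(model, dataset, resp)
    return model, trace


def labels_to_constraints(labels: LabelSet, n: int) -> ConstraintSet:
    """Binary non-overlapping constraints implied by hard labels: w⁺=1 for
    same-label pairs, w⁻=1 for different-label pairs."""
    w_pos = np.zeros((n, n))
    w_neg = np.zeros((n, n))
    items = sorted(labels.labels.items())
    for a, (i, li) in enumerate(items):
        for j, lj in items[a + 1:]:
            if li == lj:
                w_pos[i, j] = w_pos[j, i] = 1.0
            else:
                w_neg[i, j] = w_neg[j, i] = 1.0
    return ConstraintSet(w_pos, w_neg)


# ---------------------------------------------------------------------------
# file formats

def read_constraints(path, ids: list[str]) -> ConstraintSet:
    """3-column TSV (id_i, id_j, signed weight in [−1,1]); positive weights
    fill w⁺, negative weights fill w⁻ with their magnitude."""
    index = {s: i for i, s in enumerate(ids)}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["a", "b", "weight"], dtype={"a": str, "b": str})
    n = len(ids)
    w_pos = np.zeros((n, n))
    w_neg = np.zeros((n, n))
    for _, row in df.iterrows():
        i, j = index[row["a"]], index[row["b"]]
        wgt = float(row["weight"])
        if not -1 <= wgt <= 1:
            raise ValueError(f"constraint weight {wgt} outside [-1, 1]")
        if wgt >= 0:
            w_pos[i, j] = w_pos[j, i] = wgt
        else:
            w_neg[i, j] = w_neg[j, i] = -wgt
    return ConstraintSet(w_pos, w_neg)


def read_labels(path, ids: list[str]) -> LabelSet:
    """2-column TSV (id, component index)."""
    index = {s: i for i, s in enumerate(ids)}
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"],
                     dtype={"id": str})
    return LabelSet({index[r["id"]]: int(r["label"])
                     for _, r in df.iterrows()})
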