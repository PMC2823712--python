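"""Atomic per-feature distributions and the naive-Bayes product component.

All distributions operate on an *encoded* representation: discrete features
are stored as float arrays of alphabet indices, continuous features as float
arrays of raw values, and missing entries as NaN in either case.  Missing
entries contribute a log-factor of exactly 0 to any density and are excluded
from all weighted-fit sums (the standard marginal-likelihood treatment).

Discrete maximum-likelihood updates apply additive pseudocount smoothing
(``DEFAULT_PSEUDOCOUNT`` per symbol), which makes the M-step a Dirichlet-MAP
update; ``log_prior`` exposes the corresponding prior term so EM can track
the objective it actually ascends.  Gaussian fits clamp the standard
deviation at ``STDEV_FLOOR`` to prevent component collapse.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "STDEV_FLOOR",
    "DEFAULT_PSEUDOCOUNT",
    "DomainError",
    "DegenerateFitError",
    "GaussianDistribution",
    "DiscreteDistribution",
    "ExponentialDistribution",
    "ProductComponent",
    "log_density",
    "weighted_fit",
    "sample_value",
    "kl_divergence",
]

#: lower bound on any fitted Gaussian standard deviation
STDEV_FLOOR = 1e-6

#: additive pseudocount per symbol in discrete weighted fits
DEFAULT_PSEUDOCOUNT = 0.1

_LOG_2PI = math.log(2.0 * math.pi)


class DomainError(ValueError):
    """An observation falls outside a distribution's support."""


class DegenerateFitError(RuntimeError):
    """A weighted fit received no effective observations (all missing or
    zero total weight); the caller decides the fallback."""


def _as_weights(values: np.ndarray, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != values.shape:
        raise ValueError(
            f"values and weights length mismatch: {values.shape} vs {w.shape}"
        )
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w


class GaussianDistribution:
    """Univariate normal with mean/stdev parameters."""

    kind = "continuous"

    def __init__(self, mean: float, stdev: float):
        if not stdev > 0:
            raise ValueError(f"stdev must be positive, got {stdev}")
        self.mean = float(mean)
        self.stdev = float(stdev)

    def __repr__(self):
        return f"GaussianDistribution(mean={self.mean:.6g}, stdev={self.stdev:.6g})"

    @property
    def n_parameters(self) -> int:
        return 2

    def log_density_codes(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        obs = ~np.isnan(x)
        z = (x[obs] - self.mean) / self.stdev
        out[obs] = -0.5 * (z * z + _LOG_2PI) - math.log(self.stdev)
        return out

    def fit_weighted(self, x: np.ndarray, weights, stdev_floor: float = STDEV_FLOOR
                     ) -> "GaussianDistribution":
        x = np.asarray(x, dtype=float)
        w = _as_weights(x, weights)
        obs = ~np.isnan(x)
        x, w = x[obs], w[obs]
        total = w.sum()
        if x.size == 0 or total <= 0:
            raise DegenerateFitError("Gaussian fit with zero effective weight")
        mean = float(np.dot(w, x) / total)
        var = float(np.dot(w, (x - mean) ** 2) / total)
        return GaussianDistribution(mean, max(math.sqrt(var), stdev_floor))

    def sample_codes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.stdev, size=size)

    def log_prior(self) -> float:
        return 0.0

    def to_dict(self) -> dict:
        return {"type": "gaussian", "mean": self.mean, "stdev": self.stdev}


class DiscreteDistribution:
    """Categorical distribution over an ordered symbol alphabet."""

    kind = "discrete"

    def __init__(self, alphabet: Sequence[str], probs,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT):
        alphabet = tuple(str(s) for s in alphabet)
        if len(set(alphabet)) != len(alphabet):
            raise ValueError("alphabet symbols must be unique")
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(alphabet),):
            raise ValueError("probs length must match alphabet length")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1")
        self.alphabet = alphabet
        self.probs = probs
        self.pseudocount = float(pseudocount)
        self._index = {s: i for i, s in enumerate(alphabet)}

    def __repr__(self):
        body = ", ".join(f"{s}:{p:.4g}" for s, p in zip(self.alphabet, self.probs))
        return f"DiscreteDistribution({body})"

    @property
    def n_parameters(self) -> int:
        return len(self.alphabet) - 1

    def encode(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise DomainError(
                f"symbol {symbol!r} not in alphabet {''.join(self.alphabet)}"
            ) from None

    def log_density_codes(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        obs = ~np.isnan(x)
        with np.errstate(divide="ignore"):
            logp = np.log(self.probs)
        out[obs] = logp[x[obs].astype(int)]
        return out

    def fit_weighted(self, x: np.ndarray, weights,
                     pseudocount: float | None = None) -> "DiscreteDistribution":
        if pseudocount is None:
            pseudocount = self.pseudocount
        x = np.asarray(x, dtype=float)
        w = _as_weights(x, weights)
        obs = ~np.isnan(x)
        x, w = x[obs], w[obs]
        if x.size == 0 or w.sum() <= 0:
            raise DegenerateFitError("discrete fit with zero effective weight")
        counts = np.bincount(x.astype(int), weights=w, minlength=len(self.alphabet))
        counts = counts + pseudocount
        return DiscreteDistribution(self.alphabet, counts / counts.sum(),
                                    pseudocount=pseudocount)

    def sample_codes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(len(self.alphabet), size=size, p=self.probs).astype(float)

    def log_prior(self) -> float:
        # Dirichlet(1 + pseudocount) log-kernel; zero when smoothing is off
        if self.pseudocount == 0:
            return 0.0
        pos = self.probs[self.probs > 0]  # boundary zeros excluded
        return float(self.pseudocount * np.log(pos).sum())

    def to_dict(self) -> dict:
        return {"type": "discrete", "alphabet": list(self.alphabet),
                "probs": self.probs.tolist(), "pseudocount": self.pseudocount}


class ExponentialDistribution:
    """Exponential distribution, rate-parameterized (density r·e^(−r·x))."""

    kind = "continuous"

    def __init__(self, rate: float):
        if not rate > 0:
            raise ValueError(f"rate must be positive, got {rate}")
        self.rate = float(rate)

    def __repr__(self):
        return f"ExponentialDistribution(rate={self.rate:.6g})"

    @property
    def n_parameters(self) -> int:
        return 1

    def log_density_codes(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        obs = ~np.isnan(x)
        if np.any(x[obs] < 0):
            raise DomainError("exponential observations must be nonnegative")
        out[obs] = math.log(self.rate) - self.rate * x[obs]
        return out

    def fit_weighted(self, x: np.ndarray, weights) -> "ExponentialDistribution":
        x = np.asarray(x, dtype=float)
        w = _as_weights(x, weights)
        obs = ~np.isnan(x)
        x, w = x[obs], w[obs]
        total = w.sum()
        if x.size == 0 or total <= 0:
            raise DegenerateFitError("exponential fit with zero effective weight")
        sx = float(np.dot(w, x))
        if sx <= 0:
            raise DegenerateFitError("exponential fit with zero weighted sum")
        return ExponentialDistribution(total / sx)

    def sample_codes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.exponential(1.0 / self.rate, size=size)

    def log_prior(self) -> float:
        return 0.0

    def to_dict(self) -> dict:
        return {"type": "exponential", "rate": self.rate}


class ProductComponent:
    """Naive-Bayes component: an independent per-feature distribution list.

    The joint log density of a row is the sum of per-feature log densities;
    missing entries contribute 0.
    """

    def __init__(self, feature_dists: Sequence):
        self.feature_dists = list(feature_dists)
        if not self.feature_dists:
            raise ValueError("component needs at least one feature distribution")

    @property
    def p(self) -> int:
        return len(self.feature_dists)

    @property
    def n_parameters(self) -> int:
        return sum(d.n_parameters for d in self.feature_dists)

    def log_density_rows(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"row arity {X.shape[1]} != component arity {self.p}")
        out = np.zeros(X.shape[0])
        for j, dist in enumerate(self.feature_dists):
            out += dist.log_density_codes(X[:, j])
        return out

    def fit_weighted(self, X: np.ndarray, weights) -> "ProductComponent":
        X = np.asarray(X, dtype=float)
        new = []
        for j, dist in enumerate(self.feature_dists):
            try:
                new.append(dist.fit_weighted(X[:, j], weights))
            except DegenerateFitError:
                new.append(dist)  # hold parameters on an all-missing column
        return ProductComponent(new)

    def sample_rows(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cols = [d.sample_codes(rng, size) for d in self.feature_dists]
        return np.column_stack(cols)

    def log_prior(self) -> float:
        return sum(d.log_prior() for d in self.feature_dists)

    def to_dict(self) -> dict:
        return {"type": "product",
                "features": [d.to_dict() for d in self.feature_dists]}


# ---------------------------------------------------------------------------
# functional surface

def _encode_value(dist, value):
    """Map a raw observation (symbol or number) to encoded form; NaN if it is
    the missing sentinel."""
    if value is None:
        return np.nan
    if isinstance(dist, DiscreteDistribution):
        if isinstance(value, float) and math.isnan(value):
            return np.nan
        return float(dist.encode(str(value)))
    v = float(value)
    return v


def log_density(dist, value, missing_marker: str | None = "?") -> float:
    """Log density of one observation; the missing marker contributes 0."""
    if value is None or (isinstance(value, str) and value == missing_marker):
        return 0.0
    code = _encode_value(dist, value)
    return float(dist.log_density_codes(np.array([code]))[0])


def product_log_density(component: ProductComponent, row,
                        missing_marker: str | None = "?") -> float:
    """Joint naive-Bayes log density of one raw-valued row."""
    if len(row) != component.p:
        raise ValueError(f"row length {len(row)} != component arity {component.p}")
    return sum(log_density(d, v, missing_marker)
               for d, v in zip(component.feature_dists, row))


def weighted_fit(dist, values, weights, **kwargs):
    """Weighted maximum-likelihood (discrete: Dirichlet-MAP) refit of ``dist``.

    ``values`` are encoded observations (codes/floats, NaN = missing).
    Returns a new distribution of the same type.
    """
    return dist.fit_weighted(np.asarray(values, dtype=float), weights, **kwargs)


def sample_value(dist, rng: np.random.Generator):
    """Draw one encoded observation from ``dist``."""
    return dist.sample_codes(rng, 1)[0]


def kl_divergence(d1, d2) -> float:
    """KL(d1 || d2) between two distributions of the same type (closed form)."""
    if isinstance(d1, DiscreteDistribution) and isinstance(d2, DiscreteDistribution):
        if d1.alphabet != d2.alphabet:
            raise ValueError("KL between discrete distributions needs one alphabet")
        p, q = d1.probs, d2.probs
        mask = p > 0
        if np.any(q[mask] == 0):
            return math.inf
        return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))
    if isinstance(d1, GaussianDistribution) and isinstance(d2, GaussianDistribution):
        return (math.log(d2.stdev / d1.stdev)
                + (d1.stdev ** 2 + (d1.mean - d2.mean) ** 2) / (2 * d2.stdev ** 2)
                - 0.5)
    if isinstance(d1, ExponentialDistribution) and isinstance(d2, ExponentialDistribution):
        return math.log(d1.rate / d2.rate) + d2.rate / d1.rate - 1.0
    raise TypeError(f"no closed-form KL for {type(d1).__name__} vs {type(d2).__name__}")
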