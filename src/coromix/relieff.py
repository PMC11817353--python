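"""Multi-class ReliefF feature weighting.

For every sample (all ``n`` samples are used as anchors), the algorithm
finds the ``k`` nearest *hits* (same class) and, for each other class, the
``k`` nearest *misses*, by Manhattan distance on range-normalized features.
Neighbors are discounted by an exponential rank weight
``exp(-(rank/sigma)^2)`` normalized to sum to one within each neighbor
group.  Features close in hits are rewarded, features close in misses are
penalized, with miss contributions scaled by ``P(C)/(1 - P(class(x)))``
under empirical class priors.  The result is one importance weight per
feature column; weights are typically in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


class DegenerateLabelsError(ValueError):
    def __init__(self):
        super().__init__("degenerate-labels: need at least 2 classes")


@dataclass(frozen=True)
class ReliefFParams:
    """``k_neighbors`` and ``sigma`` follow the classical multi-class
    formulation; priors are always empirical class frequencies."""

    k_neighbors: int = 10
    sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class WeightVector:
    """Per-feature importance weights plus summary statistics."""

    weights: np.ndarray = field(repr=False)

    @property
    def max(self) -> float:
        return float(self.weights.max())

    @property
    def min(self) -> float:
        return float(self.weights.min())

    @property
    def mean(self) -> float:
        return float(self.weights.mean())

    def __len__(self) -> int:
        return len(self.weights)


def _rank_weights(k: int, sigma: float) -> np.ndarray:
    d = np.exp(-(((np.arange(1, k + 1)) / sigma) ** 2))
    return d / d.sum()


def relieff_weights(
    X: np.ndarray, y: np.ndarray, params: ReliefFParams | None = None
) -> WeightVector:
    """ReliefF importance weights for an (n, p) feature matrix.

    Features with zero range contribute nothing and receive weight 0.
    Classes with fewer than ``k_neighbors + 1`` members use all available
    neighbors.  Deterministic: neighbor ties are broken by sample index.
    """
    params = params or ReliefFParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, p = X.shape
    if p == 0:
        return WeightVector(weights=np.zeros(0))
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise DegenerateLabelsError()
    if n < 2:
        raise ValueError("need at least 2 samples")

    rng_span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(rng_span > 0, rng_span, 1.0)
    Xn = X / safe  # diff(f, a, b) = |a_f - b_f| / range_f

    priors = np.bincount(y_idx, minlength=classes.size) / n
    D = cdist(Xn, Xn, metric="cityblock")
    class_members = [np.flatnonzero(y_idx == c) for c in range(classes.size)]

    W = np.zeros(p)
    k = params.k_neighbors
    for i in range(n):
        ci = y_idx[i]
        for c, members in enumerate(class_members):
            cand = members[members != i] if c == ci else members
            if cand.size == 0:
                continue
            kk = min(k, cand.size)
            order = cand[np.argsort(D[i, cand], kind="stable")][:kk]
            d_norm = _rank_weights(kk, params.sigma)
            diffs = np.abs(Xn[i] - Xn[order])  # (kk, p)
            contrib = d_norm @ diffs
            if c == ci:
                W -= contrib / n
            else:
                W += (priors[c] / (1.0 - priors[ci])) * contrib / n
    W[rng_span == 0] = 0.0
    return WeightVector(weights=W)


def rank_features(weights: WeightVector | np.ndarray) -> np.ndarray:
    """Feature indices sorted by descending weight; ties keep index order."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    return np.argsort(-w, kind="stable")
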