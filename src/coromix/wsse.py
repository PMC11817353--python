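"""Weighted subspace SVM ensemble (WSSE).

Features ranked by ReliefF importance are split into ``k`` contiguous,
near-equal subspaces (highest-ranked features in the first subspace).  One
multi-class SVM is trained per subspace on that subspace's columns only.
At prediction time each subspace casts its predicted label with a vote mass
equal to the (non-negative) sum of the ReliefF weights of its features, and
the label with the largest total mass wins; ties go to the label backed by
the earliest (highest-importance) subspace.

An alternative integer-replication vote (subspace ``i`` of ``k`` casts
``k - i`` extra copies) is available via ``vote_mode="replication"``; both
schemes honor "more important subspaces count more".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .relieff import WeightVector, rank_features


class TooManySubspacesError(ValueError):
    def __init__(self, k: int, p: int):
        super().__init__(f"too-many-subspaces: k={k} > p={p}")


@dataclass(frozen=True)
class SubspacePartition:
    """Ordered disjoint feature-index blocks with non-increasing vote mass."""

    subspaces: tuple[tuple[int, ...], ...]
    vote_mass: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.subspaces)


@dataclass(frozen=True)
class SVMOptions:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (p_subspace * var)
    standardize: bool = True

    def make_pipeline(self) -> Pipeline:
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(
            ("svm", SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                        decision_function_shape="ovo"))
        )
        return Pipeline(steps)


@dataclass
class WSSEModel:
    partition: SubspacePartition
    classifiers: list[Pipeline] = field(repr=False)
    classes: np.ndarray = field(repr=False)
    options: SVMOptions = field(default_factory=SVMOptions)
    vote_mode: str = "mass"
    n_features: int = 0
    #: per-subspace predictions (k, m) and vote matrix (m, n_classes) of the
    #: most recent predict call, retained for inspection
    last_prediction_matrix: np.ndarray | None = field(default=None, repr=False)
    last_voting_matrix: np.ndarray | None = field(default=None, repr=False)


def partition_subspaces(weights: WeightVector | np.ndarray, k: int) -> SubspacePartition:
    """Split the descending-rank feature order into ``k`` contiguous blocks.

    Block sizes are ``ceil(p/k)`` or ``floor(p/k)`` with the larger blocks
    first; the vote mass of a block is the sum of its ReliefF weights,
    floored at zero.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    p = w.size
    if k < 1 or p == 0:
        raise ValueError("need k >= 1 and at least one feature")
    if k > p:
        raise TooManySubspacesError(k, p)
    order = rank_features(w)
    base, extra = divmod(p, k)
    subspaces = []
    masses = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        block = tuple(int(j) for j in order[pos : pos + size])
        subspaces.append(block)
        masses.append(max(float(w[list(block)].sum()), 0.0))
        pos += size
    return SubspacePartition(subspaces=tuple(subspaces), vote_mass=tuple(masses))


def fit_wsse(
    X: np.ndarray,
    y: np.ndarray,
    partition: SubspacePartition,
    options: SVMOptions | None = None,
    vote_mode: str = "mass",
) -> WSSEModel:
    """Train one SVM per subspace on that subspace's columns."""
    options = options or SVMOptions()
    if vote_mode not in ("mass", "replication"):
        raise ValueError("vote_mode must be 'mass' or 'replication'")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    max_col = max(max(block) for block in partition.subspaces)
    if max_col >= X.shape[1]:
        raise IndexError(
            f"partition references column {max_col} but X has {X.shape[1]} features"
        )
    classifiers = []
    for block in partition.subspaces:
        clf = options.make_pipeline()
        clf.fit(X[:, list(block)], y)
        classifiers.append(clf)
    return WSSEModel(
        partition=partition,
        classifiers=classifiers,
        classes=np.unique(y),
        options=options,
        vote_mode=vote_mode,
        n_features=X.shape[1],
    )


def predict_wsse(model: WSSEModel, X: np.ndarray) -> np.ndarray:
    """Importance-weighted majority vote over the subspace SVMs."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    m = X.shape[0]
    k = model.partition.k
    classes = model.classes
    class_pos = {c: i for i, c in enumerate(classes)}
    preds = np.empty((k, m), dtype=classes.dtype)
    for i, (block, clf) in enumerate(zip(model.partition.subspaces, model.classifiers)):
        preds[i] = clf.predict(X[:, list(block)])
    if model.vote_mode == "mass":
        masses = np.asarray(model.partition.vote_mass)
    else:
        masses = np.arange(k, 0, -1, dtype=float)  # k - i copies
    votes = np.zeros((m, classes.size))
    for i in range(k):
        rows = np.array([class_pos[c] for c in preds[i]])
        votes[np.arange(m), rows] += masses[i]
    # argmax with ties resolved in favor of the earliest subspace's label
    out = np.empty(m, dtype=classes.dtype)
    for j in range(m):
        best = votes[j].max()
        tied = set(classes[np.flatnonzero(votes[j] == best)])
        for i in range(k):
            if preds[i, j] in tied:
                out[j] = preds[i, j]
                break
        else:  # no subspace predicted a tied class (possible only if mass 0)
            out[j] = classes[int(np.argmax(votes[j]))]
    model.last_prediction_matrix = preds
    model.last_voting_matrix = votes
    return out
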