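"""Cross-validated evaluation: folds, confusion matrices, per-class metrics,
and the four-arm ablation ladder.

The ladder compares, under one stratified fold plan:

    (a) the end-to-end softmax ConvMixer;
    (b) ConvMixer ``fc_embed`` features -> a single SVM;
    (c) features -> top-q ReliefF-selected columns -> SVM;
    (d) features -> ReliefF-weighted subspace SVM ensemble (WSSE).

ReliefF weights, feature selection, SVMs and the ensemble are fitted
strictly inside each training fold; test folds only ever contribute
predictions.  Metrics are one-vs-rest per class: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), F-score 2TP/(2TP+FP+FN), and
pooled accuracy trace/total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ecg_io import CLASS_NAMES
from .convmixer import ModelConfig, TrainOptions, build_model, train_model
from .relieff import ReliefFParams, rank_features, relieff_weights
from .wsse import SVMOptions, fit_wsse, partition_subspaces, predict_wsse

ARMS = ("a", "b", "c", "d")
ARM_NAMES = {
    "a": "convmixer_softmax",
    "b": "convmixer_svm",
    "c": "convmixer_relieff_svm",
    "d": "convmixer_wsse",
}


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint, covering, stratified test-index lists; seeded."""

    k: int
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.asarray(self.folds[fold], dtype=int)

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.folds[fold])
        n = sum(len(f) for f in self.folds)
        return np.asarray([i for i in range(n) if i not in test], dtype=int)


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified fold plan: per-class counts per fold differ by at most 1."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"a class has only {counts.min()} members for {k} folds; "
            "some folds will miss it",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # the warning above already covers the under-populated-class case
        warnings.simplefilter("ignore", UserWarning)
        folds = tuple(
            tuple(int(i) for i in test)
            for _, test in skf.split(np.zeros(y.size), y)
        )
    return FoldPlan(k=k, folds=folds, seed=seed)


def confusion_matrix(y_true, y_pred, classes=CLASS_NAMES) -> np.ndarray:
    """Counts[i, j] = #{true == classes[i], predicted == classes[j]}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    pos = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in pos or p not in pos:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        cm[pos[t], pos[p]] += 1
    return cm


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """One-vs-rest metrics from 2x2 counts; division by zero yields 0."""
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    out = {
        "sensitivity": safe(tp, tp + fn, "sensitivity"),
        "specificity": safe(tn, tn + fp, "specificity"),
        "precision": safe(tp, tp + fp, "precision"),
        "f_score": safe(2 * tp, 2 * tp + fp + fn, "f_score"),
    }
    out["zero_division_flags"] = flags
    return out


@dataclass(frozen=True)
class MetricsTable:
    """Per-class one-vs-rest metrics plus pooled accuracy."""

    per_class: dict[str, dict[str, float]]
    accuracy: float

    def as_dict(self) -> dict:
        return {"per_class": self.per_class, "accuracy": self.accuracy}


def per_class_metrics(cm: np.ndarray, classes=CLASS_NAMES) -> MetricsTable:
    cm = np.asarray(cm)
    total = cm.sum()
    table: dict[str, dict[str, float]] = {}
    for i, name in enumerate(classes):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        table[name] = binary_metrics(tp, fp, fn, tn)
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return MetricsTable(per_class=table, accuracy=accuracy)


# ---------------------------------------------------------------------------
# ablation ladder


@dataclass(frozen=True)
class AblationConfig:
    """Everything the four arms need, beyond the shared fold plan."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainOptions = field(default_factory=TrainOptions)
    relieff: ReliefFParams = field(default_factory=ReliefFParams)
    svm: SVMOptions = field(default_factory=SVMOptions)
    folds: int = 10
    top_q: int = 500  # arm (c) selection size
    wsse_k: int = 10
    vote_mode: str = "mass"
    seed: int = 0
    arms: tuple[str, ...] = ARMS


def fit_feature_arms(
    F_train: np.ndarray,
    y_train: np.ndarray,
    config: AblationConfig,
):
    """Fit arms (b), (c), (d) on training-fold features only.

    Returns a dict of predictors, each mapping an (m, p) feature matrix to
    label predictions.  Exposed separately so leakage freedom (no test-fold
    influence on fitting) is directly testable.
    """
    fitted = {}
    if "b" in config.arms:
        clf_b = config.svm.make_pipeline()
        clf_b.fit(F_train, y_train)
        fitted["b"] = clf_b.predict
    need_relieff = "c" in config.arms or "d" in config.arms
    if need_relieff:
        wv = relieff_weights(F_train, y_train, config.relieff)
    if "c" in config.arms:
        q = min(config.top_q, F_train.shape[1])
        top = rank_features(wv)[:q]
        clf_c = config.svm.make_pipeline()
        clf_c.fit(F_train[:, top], y_train)
        fitted["c"] = lambda F, top=top, clf=clf_c: clf.predict(F[:, top])
    if "d" in config.arms:
        part = partition_subspaces(wv, min(config.wsse_k, F_train.shape[1]))
        wmodel = fit_wsse(F_train, y_train, part, config.svm, config.vote_mode)
        fitted["d"] = lambda F, m=wmodel: predict_wsse(m, F)
    return fitted


def run_ablation(
    X_images: np.ndarray,
    labels: np.ndarray,
    config: AblationConfig,
) -> dict:
    """Run the requested arms under one stratified fold plan.

    ``X_images``: (n, 12, size, size, 3) spectrogram tensors; ``labels``:
    class-name strings.  Returns a JSON-serializable report with pooled
    confusion matrices, per-class metrics and accuracies per arm.
    """
    labels = np.asarray(labels)
    y_idx = np.array([CLASS_NAMES.index(l) for l in labels])
    plan = stratified_kfold(labels, k=config.folds, seed=config.seed)
    pooled: dict[str, list] = {arm: [] for arm in config.arms}
    pooled_true: list = []

    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        model = build_model(config.model, seed=config.seed + fold)
        train_model(model, X_images[tr], y_idx[tr], config.train)
        if "a" in config.arms:
            probs = model.predict_proba(X_images[te])
            pooled["a"].extend(np.asarray(CLASS_NAMES)[probs.argmax(axis=1)])
        feature_arms = [arm for arm in config.arms if arm in ("b", "c", "d")]
        if feature_arms:
            F_tr = model.extract_features(X_images[tr])
            F_te = model.extract_features(X_images[te])
            fitted = fit_feature_arms(F_tr, labels[tr], config)
            for arm in feature_arms:
                pooled[arm].extend(fitted[arm](F_te))
        pooled_true.extend(labels[te])

    report: dict = {
        "n": int(labels.size),
        "folds": plan.k,
        "seed": config.seed,
        "arms": {},
    }
    for arm in config.arms:
        cm = confusion_matrix(pooled_true, pooled[arm])
        metrics = per_class_metrics(cm)
        report["arms"][arm] = {
            "name": ARM_NAMES[arm],
            "confusion_matrix": cm.tolist(),
            "metrics": metrics.as_dict(),
            "accuracy": metrics.accuracy,
        }
    return report


def write_confusion_csvs(report: dict, out_dir) -> None:
    """One CSV per arm (rows true class, columns predicted class)."""
    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for arm, entry in report["arms"].items():
        frame = pd.DataFrame(entry["confusion_matrix"],
                             index=list(CLASS_NAMES), columns=list(CLASS_NAMES))
        frame.to_csv(out_dir / f"confusion_{entry['name']}.csv")
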