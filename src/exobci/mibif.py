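"""Mutual-information-based best individual feature (MIBIF) selection.

Features are ranked by estimated mutual information with the binary class
label; the top k (default candidates 4-10) are kept, optionally completed
with each CSP component's within-band mirror.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .filterbank import N_SELECTED


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning; constant input maps to one bin."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def discrete_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Exact plug-in MI (bits) of two discrete-valued arrays."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = x.size
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_information(feature_values, labels, n_bins: int | None = None) -> float:
    """MI (bits) between a continuous per-trial feature and the class label.

    The feature is discretized by quantile binning with
    B = min(8, floor(sqrt(n))) bins, then the exact discrete MI sum is
    evaluated.  A constant feature yields 0.
    """
    x = np.asarray(feature_values, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("need at least 2 trials per class")
    if np.ptp(x) == 0:
        return 0.0
    if n_bins is None:
        n_bins = min(8, int(np.floor(np.sqrt(x.size))))
    n_bins = max(n_bins, 2)
    return discrete_mutual_information(_discretize(x, n_bins), y)


@dataclass(frozen=True)
class MIRanking:
    """Per-feature MI estimates and the descending-MI permutation."""

    mi: np.ndarray
    order: tuple
    classes: tuple = ("A", "B")

    def __post_init__(self):
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of feature indices")


@dataclass(frozen=True)
class SelectionK:
    """Chosen k and the resulting feature indices (possibly pair-completed)."""

    k: int
    indices: tuple
    pair_completion: bool


def rank_features(features: np.ndarray, labels, classes: tuple = ("A", "B")) -> MIRanking:
    """Rank feature columns by MI with the label, descending; ties keep lower index."""
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (trials x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing/non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    mi = np.array([mutual_information(X[:, j], y) for j in range(X.shape[1])])
    order = tuple(sorted(range(X.shape[1]), key=lambda j: (-mi[j], j)))
    return MIRanking(mi=mi, order=order, classes=tuple(classes))


def select_features(ranking: MIRanking, k: int,
                    pair_completion: bool = True) -> SelectionK:
    """Take the top-k ranked features.

    With pair completion, each selected feature's within-band mirror CSP
    component (slot j <-> 3-j) is added as well, so the final index count
    may exceed k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking.order):
        raise ValueError(f"k={k} exceeds the {len(ranking.order)} features")
    chosen = list(ranking.order[:k])
    if pair_completion:
        for idx in list(chosen):
            band, comp = divmod(idx, N_SELECTED)
            mirror = band * N_SELECTED + (N_SELECTED - 1 - comp)
            if mirror not in chosen:
                chosen.append(mirror)
    return SelectionK(k=k, indices=tuple(chosen), pair_completion=pair_completion)


def _default_classifier():
    return LinearSVC(C=1.0, class_weight="balanced")


def choose_k(features: np.ndarray, labels, candidates=range(4, 11),
             pair_completion: bool = True, n_splits: int = 5,
             classifier_factory=_default_classifier, seed: int = 0) -> int:
    """Pick k maximizing stratified cross-validated accuracy; ties -> smaller k.

    Mimics the per-subject empirical choice of k by cross-validation on the
    training features.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 10):
        raise ValueError("need >= 10 trials per class to choose k")
    candidates = sorted(candidates)
    best_k, best_acc = candidates[0], -1.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for k in candidates:
        accs = []
        for train, test in skf.split(X, y):
            ranking = rank_features(X[train], y[train])
            sel = select_features(ranking, k, pair_completion)
            clf = classifier_factory()
            clf.fit(X[train][:, sel.indices], y[train])
            accs.append(np.mean(clf.predict(X[test][:, sel.indices]) == y[test]))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return best_k
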