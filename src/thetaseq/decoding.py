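"""Decoding sequence position from phase of firing (or from rates).

Per-trial mean phases serve as predictors for a 4-class RBF-kernel SVM
(one-vs-one) with repeated stratified 85/15 train/test splits; chance is
25%. Significance comes from a label-shuffle null (labels permuted across
trials, the full decoder re-run per shuffle). Circular predictors are
embedded as unit-circle coordinates (cos, sin) so that wrap-around
neighbours stay close in feature space.

``PhasePositionDecoder`` is a scikit-learn compatible classifier (fit /
predict / score, get_params / set_params) and can be dropped into
sklearn model-selection utilities directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DecodingResult",
    "PhasePositionDecoder",
    "embed_phases",
    "decode_position",
    "shuffle_null",
    "pseudo_population",
]


@dataclass
class DecodingResult:
    accuracies: np.ndarray          # held-out accuracy per repeat
    mean_accuracy: float
    null: np.ndarray | None = None  # mean accuracy per label shuffle
    p_value: float | None = None
    scope: str = "single_unit"      # single_unit | pseudo_population
    feature: str = "phase"          # phase | rate


def embed_phases(phases) -> np.ndarray:
    """Map angles (n_trials,) or (n_trials, n_units) to (cos, sin) columns."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim == 1:
        phases = phases[:, None]
    return np.concatenate([np.cos(phases), np.sin(phases)], axis=1)


class PhasePositionDecoder(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM position decoder over circular features.

    Parameters
    ----------
    circular : bool
        If True (default) input columns are angles in radians and are
        embedded as (cos, sin) pairs before the kernel; set False for
        rate features.
    C : float
        SVM regularization (unit by default; no inner search, for
        determinism).
    gamma : 'median' or float
        RBF scale; 'median' uses 1 / (2 * median pairwise distance**2)
        of the training features.
    """

    def __init__(self, circular: bool = True, C: float = 1.0, gamma="median"):
        self.circular = circular
        self.C = C
        self.gamma = gamma

    def _features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.circular:
            X = np.concatenate([np.cos(X), np.sin(X)], axis=1)
        return X

    def fit(self, X, y):
        F = self._features(X)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes")
        gamma = self.gamma
        if gamma == "median":
            d = pairwise_distances(F)
            med = np.median(d[np.triu_indices_from(d, k=1)])
            gamma = 1.0 / (2.0 * med**2) if med > 0 else 1.0
        self.gamma_ = float(gamma)
        self.svm_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma_,
                        decision_function_shape="ovo")
        self.svm_.fit(F, y)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict(self._features(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _stratified_splits(labels, train_frac, n_repeats, rng):
    # stratification guarantees every class in both halves, provided the
    # held-out set has room for at least one trial per class
    n = len(labels)
    n_classes = np.unique(labels).size
    test_size = max(int(round((1.0 - train_frac) * n)), n_classes)
    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_size,
                                 random_state=int(rng.integers(2**31)))
    return list(sss.split(np.zeros((n, 1)), labels))


def decode_position(features, labels, train_frac: float = 0.85,
                    n_repeats: int = 20, rng=None, circular: bool = True,
                    scope: str = "single_unit",
                    feature: str = "phase") -> DecodingResult:
    """Mean held-out accuracy over repeated stratified train/test splits."""
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 trials")
    accs = []
    for train, test in _stratified_splits(labels, train_frac, n_repeats, rng):
        dec = PhasePositionDecoder(circular=circular)
        dec.fit(np.asarray(features)[train], labels[train])
        accs.append(dec.score(np.asarray(features)[test], labels[test]))
    accs = np.asarray(accs)
    return DecodingResult(accuracies=accs, mean_accuracy=float(accs.mean()),
                          scope=scope, feature=feature)


def shuffle_null(features, labels, n_shuffles: int = 101,
                 train_frac: float = 0.85, n_repeats: int = 5, rng=None,
                 circular: bool = True, scope: str = "single_unit",
                 feature: str = "phase") -> DecodingResult:
    """Observed decoding vs a label-shuffle null.

    Each shuffle randomly reassigns position labels across trials and
    re-runs the decoder; p is the add-one rank of the observed mean
    accuracy in the null.
    """
    if n_shuffles < 20:
        import warnings
        warnings.warn("fewer than 20 shuffles: coarse p-value resolution",
                      stacklevel=2)
    rng = np.random.default_rng(rng)
    observed = decode_position(features, labels, train_frac, n_repeats, rng,
                               circular, scope, feature)
    labels = np.asarray(labels)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels.size)
        res = decode_position(features, labels[perm], train_frac, n_repeats,
                              rng, circular, scope, feature)
        null[s] = res.mean_accuracy
    observed.null = null
    observed.p_value = float((1 + np.sum(null >= observed.mean_accuracy))
                             / (1 + n_shuffles))
    return observed


def pseudo_population(sample_sets, rng=None, n_pseudo_per_class=None):
    """Assemble pseudo-trials across (non-simultaneous) units.

    For each class, each unit's trials are sampled without replacement and
    paired at random; the common trial count per class is the minimum over
    contributing units (units lacking >= 2 trials in any class are dropped).
    Returns ``(angles, labels, kept_units)`` with ``angles`` of shape
    (n_pseudo_trials, n_units); embed with ``circular=True`` for decoding.
    """
    rng = np.random.default_rng(rng)
    sets = list(sample_sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 units for a pseudo-population")
    classes = np.unique(np.concatenate([s.conditions for s in sets]))
    kept = []
    for s in sets:
        counts = {c: int(np.sum(s.conditions == c)) for c in classes}
        if all(v >= 2 for v in counts.values()):
            kept.append(s)
    if len(kept) < 2:
        raise ValueError("fewer than 2 units have >= 2 trials in every class")
    per_class = {c: min(int(np.sum(s.conditions == c)) for s in kept)
                 for c in classes}
    if n_pseudo_per_class is not None:
        per_class = {c: min(v, n_pseudo_per_class) for c, v in per_class.items()}
    blocks, labels = [], []
    for c in classes:
        m = per_class[c]
        cols = []
        for s in kept:
            ph = s.phases[s.conditions == c]
            cols.append(rng.choice(ph, size=m, replace=False))
        blocks.append(np.stack(cols, axis=1))
        labels.append(np.full(m, c))
    return np.concatenate(blocks), np.concatenate(labels), kept
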