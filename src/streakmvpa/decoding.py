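"""Linear decoders, leave-one-run-out CV, and cross-condition generalization.

Three interchangeable binary classifiers distinguish the 45 deg vs 135 deg
labels of voxel patterns: a linear SVM (scikit-learn), a pattern-correlation
classifier (nearest class template by Pearson correlation), and a
shrinkage-regularized pooled-covariance LDA.  Correlation and LDA are
implemented here in full so their decision rules can be checked against
brute-force evaluation.

Ties (zero decision values) are broken deterministically toward the 45 deg
class; with continuous data they have probability ~0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import PatternSet
from .synthetic_data import CLASS_LABELS, STIMULUS_TYPES

__all__ = [
    "CLASSIFIER_KINDS",
    "LinearModel",
    "DecodingResult",
    "train",
    "leave_one_run_out_cv",
    "cross_generalize",
    "full_matrix",
]

CLASSIFIER_KINDS = ("svm", "correlation", "lda")
NEG_CLASS, POS_CLASS = CLASS_LABELS  # 45 -> negative decision, 135 -> positive


@dataclass
class LinearModel:
    """A trained binary decoder over voxel patterns.

    For ``svm``/``lda`` the decision value is ``w . x + b`` (positive ->
    135).  For ``correlation`` the model stores the two class-mean templates
    and the decision value is ``r(x, template_135) - r(x, template_45)``.
    """

    classifier_kind: str
    weights: np.ndarray | None = None
    bias: float = 0.0
    templates: dict[int, np.ndarray] = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.classifier_kind == "correlation":
            r_pos = _pearson_to_template(X, self.templates[POS_CLASS])
            r_neg = _pearson_to_template(X, self.templates[NEG_CLASS])
            return r_pos - r_neg
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d > 0, POS_CLASS, NEG_CLASS)


def _pearson_to_template(X: np.ndarray, template: np.ndarray) -> np.ndarray:
    xc = X - X.mean(axis=1, keepdims=True)
    tc = template - template.mean()
    xn = np.linalg.norm(xc, axis=1)
    tn = np.linalg.norm(tc)
    denom = xn * tn
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / denom
    return np.where(denom > 0, r, 0.0)


def train(
    pset: PatternSet,
    kind: str = "correlation",
    svm_c: float = 1.0,
    lda_shrinkage: float = 0.1,
) -> LinearModel:
    """Fit a binary decoder on every pattern in ``pset``.

    Deterministic given the data.  ``lda_shrinkage`` mixes the pooled
    covariance with a scaled identity: ``S = (1-l)*S_pooled + l*(tr(S)/p)*I``,
    which keeps the discriminant defined when blocks are fewer than voxels.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    X = np.asarray(pset.patterns, dtype=float)
    y = np.asarray(pset.class_label, dtype=int)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError(f"training set contains a single class: {present.tolist()}")

    if kind == "correlation":
        templates = {c: X[y == c].mean(axis=0) for c in CLASS_LABELS}
        return LinearModel(classifier_kind=kind, templates=templates)

    if kind == "lda":
        mu = {c: X[y == c].mean(axis=0) for c in CLASS_LABELS}
        centered = np.concatenate([X[y == c] - mu[c] for c in CLASS_LABELS])
        dof = max(len(X) - 2, 1)
        pooled = centered.T @ centered / dof
        p = pooled.shape[0]
        shrunk = (1.0 - lda_shrinkage) * pooled + lda_shrinkage * (np.trace(pooled) / p) * np.eye(p)
        w = np.linalg.solve(shrunk, mu[POS_CLASS] - mu[NEG_CLASS])
        b = -float(w @ (mu[POS_CLASS] + mu[NEG_CLASS]) / 2.0)
        return LinearModel(classifier_kind=kind, weights=w, bias=b)

    from sklearn.svm import SVC

    clf = SVC(kernel="linear", C=svm_c)
    clf.fit(X, y)  # sklearn orders classes ascending: decision > 0 -> 135
    return LinearModel(classifier_kind=kind, weights=clf.coef_.ravel(), bias=float(clf.intercept_[0]))


@dataclass
class DecodingResult:
    """Predictions and accuracy for one (ROI, train-type, test-type) cell."""

    roi_id: str
    train_type: str
    test_type: str
    classifier_kind: str
    scheme: str
    per_fold_predictions: list[tuple[int, int, int]]  # (true, predicted, test run)

    @property
    def n_total(self) -> int:
        return len(self.per_fold_predictions)

    @property
    def n_correct(self) -> int:
        return sum(t == p for t, p, _ in self.per_fold_predictions)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    def fold_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold_predictions, columns=["true", "predicted", "fold"])
        df.insert(0, "roi", self.roi_id)
        return df


def _check_fold(train_runs: np.ndarray, y_train: np.ndarray, test_run: int) -> None:
    if len(np.unique(y_train)) < 2:
        raise ValueError(f"fold with test run {test_run}: a class is missing from the training runs")


def leave_one_run_out_cv(pset: PatternSet, stimulus_type: str, kind: str = "correlation") -> DecodingResult:
    """Within-type decoding: each run serves once as the held-out test set.

    For the default design this yields 10 folds x 2 test patterns = 20
    predictions per participant per ROI.
    """
    sub = pset.of_type(stimulus_type)
    runs = np.unique(sub.run_index)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    for r in runs:
        if len(np.unique(sub.class_label[sub.run_index == r])) < 2:
            raise ValueError(f"run {int(r)} is missing a class for stimulus type {stimulus_type!r}")
    preds: list[tuple[int, int, int]] = []
    for r in runs:
        train_mask = sub.run_index != r
        _check_fold(sub.run_index[train_mask], sub.class_label[train_mask], int(r))
        model = train(sub.subset(train_mask), kind)
        test = sub.subset(~train_mask)
        yhat = model.predict(test.patterns)
        preds.extend((int(t), int(p), int(r)) for t, p in zip(test.class_label, yhat))
    return DecodingResult(pset.roi_id, stimulus_type, stimulus_type, kind, "loro", preds)


def cross_generalize(
    pset: PatternSet,
    train_type: str,
    test_type: str,
    kind: str = "correlation",
    scheme: str = "all-blocks",
) -> DecodingResult:
    """Train on one stimulus type, test on another.

    ``all-blocks`` (default) trains on every block of ``train_type`` and
    tests on every block of ``test_type`` — no leakage is possible because a
    block has exactly one stimulus type.  ``run-matched`` mirrors the
    leave-one-run-out folds for comparability with within-type decoding.
    """
    if train_type == test_type:
        raise ValueError("cross_generalize requires train_type != test_type")
    tr = pset.of_type(train_type)
    te = pset.of_type(test_type)
    preds: list[tuple[int, int, int]] = []
    if scheme == "all-blocks":
        model = train(tr, kind)
        yhat = model.predict(te.patterns)
        preds = [(int(t), int(p), int(r)) for t, p, r in zip(te.class_label, yhat, te.run_index)]
    elif scheme == "run-matched":
        for r in np.unique(te.run_index):
            train_mask = tr.run_index != r
            _check_fold(tr.run_index[train_mask], tr.class_label[train_mask], int(r))
            model = train(tr.subset(train_mask), kind)
            test = te.subset(te.run_index == r)
            yhat = model.predict(test.patterns)
            preds.extend((int(t), int(p), int(r)) for t, p in zip(test.class_label, yhat))
    else:
        raise ValueError(f"unknown generalization scheme {scheme!r}")
    return DecodingResult(pset.roi_id, train_type, test_type, kind, scheme, preds)


def matrix_cells() -> list[tuple[str, str]]:
    """The 9 (train, test) cells: 3 within-type + 6 cross-type."""
    within = [(s, s) for s in STIMULUS_TYPES]
    cross = [(a, b) for a, b in itertools.permutations(STIMULUS_TYPES, 2)]
    return within + cross


def full_matrix(
    pattern_sets: dict[str, PatternSet],
    kinds: Sequence[str] = ("correlation",),
    scheme: str = "all-blocks",
    participant: str = "sub-01",
) -> pd.DataFrame:
    """Every decoding cell for every ROI of one participant, as a tidy table.

    Columns: participant, roi, classifier, train_type, test_type, scheme,
    n_correct, n_total, accuracy.  With 5 ROIs this is 45 cells per
    classifier kind.
    """
    rows = []
    for roi, pset in pattern_sets.items():
        for kind in kinds:
            for train_type, test_type in matrix_cells():
                if train_type == test_type:
                    res = leave_one_run_out_cv(pset, train_type, kind)
                else:
                    res = cross_generalize(pset, train_type, test_type, kind, scheme)
                rows.append(
                    {
                        "participant": participant,
                        "roi": roi,
                        "classifier": kind,
                        "train_type": train_type,
                        "test_type": test_type,
                        "scheme": res.scheme,
                        "n_correct": res.n_correct,
                        "n_total": res.n_total,
                        "accuracy": res.accuracy,
                    }
                )
    return pd.DataFrame(rows)
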