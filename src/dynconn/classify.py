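"""Repeated cross-validated SVM evaluation.

Protocol: a support-vector machine with a polynomial kernel of order 1
(affine: linear plus constant offset), 5-fold stratified cross-validation
repeated 50 times with reshuffled folds, per-repetition accuracy pooled over
the five test folds. The report carries the maximum and mean accuracy over
repetitions, their standard deviation, and sensitivity/specificity of the
pooled predictions (positive class = first class of the task).

Because sample fusion places two rows per subject (one PLI-derived, one
WPLI-derived) in the feature matrix, row-random folds can place a subject's
two rows on both sides of a split. The default fold policy is row-random to
replicate the original protocol; a subject-grouped policy (both rows of a
subject always in the same fold) is provided as the leakage-free variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = ["CVProtocol", "ClassificationReport", "cross_validate", "sensitivity_specificity"]


@dataclass(frozen=True)
class CVProtocol:
    """k-fold cross-validation repeated ``repetitions`` times.

    ``fold_policy``: ``"row"`` = stratified row-random folds (the replicated
    protocol); ``"subject"`` = stratified subject-grouped folds.
    """

    k: int = 5
    repetitions: int = 50
    seed: int = 0
    fold_policy: str = "row"
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.fold_policy not in ("row", "subject"):
            raise ValueError("fold_policy must be 'row' or 'subject'")


@dataclass
class ClassificationReport:
    """Aggregate of the repeated CV runs (percentages)."""

    max_accuracy: float
    mean_accuracy: float
    std_accuracy: float
    sensitivity: float
    specificity: float
    per_rep_accuracy: np.ndarray
    task: tuple[str, str]
    n_samples: int
    n_features: int
    fold_policy: str

    def to_dict(self) -> dict:
        return {
            "task": f"{self.task[0]}-vs-{self.task[1]}",
            "max_accuracy": self.max_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "fold_policy": self.fold_policy,
        }

    def summary(self) -> str:
        return (
            f"{self.task[0]}-vs-{self.task[1]} ({self.n_samples}x{self.n_features}, "
            f"{self.fold_policy} folds): max {self.max_accuracy:.2f}%  "
            f"mean {self.mean_accuracy:.2f}%  sd {self.std_accuracy:.2f}  "
            f"sens {self.sensitivity:.2f}%  spec {self.specificity:.2f}%"
        )


def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """True-positive and true-negative rates, in percent."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no positive-class samples")
    if tn + fp == 0:
        raise ValueError("no negative-class samples")
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def _classifier(c: float) -> object:
    # degree-1 polynomial kernel = affine (linear + constant offset)
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="poly", degree=1, coef0=1.0, gamma="scale", C=c),
    )


def cross_validate(fm: FeatureMatrix, protocol: CVProtocol = CVProtocol()) -> ClassificationReport:
    """Run the repeated CV protocol on a feature matrix.

    Scaling statistics are fit within each training fold only. Accuracy per
    repetition is the pooled correct fraction over the k test folds; the
    report's sensitivity/specificity are means of the per-repetition pooled
    rates. Deterministic for a fixed protocol seed.
    """
    pos, neg = fm.task
    y = fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"binary task required, got classes {list(classes)}")
    if counts.min() < protocol.k:
        raise ValueError("each class needs at least k rows")
    x = fm.values
    groups = fm.provenance["subject"].to_numpy() if protocol.fold_policy == "subject" else None

    rng = np.random.default_rng(protocol.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=protocol.repetitions)

    accs = np.empty(protocol.repetitions)
    sens = np.empty(protocol.repetitions)
    spec = np.empty(protocol.repetitions)
    for r, rep_seed in enumerate(rep_seeds):
        if protocol.fold_policy == "subject":
            splitter = StratifiedGroupKFold(protocol.k, shuffle=True, random_state=int(rep_seed))
            splits = splitter.split(x, y, groups)
        else:
            splitter = StratifiedKFold(protocol.k, shuffle=True, random_state=int(rep_seed))
            splits = splitter.split(x, y)
        pred = np.empty(len(y), dtype=object)
        for train, test in splits:
            clf = _classifier(protocol.svm_c)
            clf.fit(x[train], y[train])
            pred[test] = clf.predict(x[test])
        accs[r] = np.mean(pred == y)
        tp = int(np.sum((pred == pos) & (y == pos)))
        fn = int(np.sum((pred != pos) & (y == pos)))
        tn = int(np.sum((pred != pos) & (y != pos)))
        fp = int(np.sum((pred == pos) & (y != pos)))
        sens[r], spec[r] = sensitivity_specificity(tp, fn, tn, fp)

    accs_pct = 100.0 * accs
    return ClassificationReport(
        max_accuracy=float(accs_pct.max()),
        mean_accuracy=float(accs_pct.mean()),
        std_accuracy=float(accs_pct.std(ddof=1)) if len(accs_pct) > 1 else 0.0,
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        per_rep_accuracy=accs_pct,
        task=fm.task,
        n_samples=x.shape[0],
        n_features=x.shape[1],
        fold_policy=protocol.fold_policy,
    )
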