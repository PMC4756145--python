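"""Leave-one-out SVM classification of connectivity feature matrices.

Each subject is held out once; the model is trained on the remaining
subjects (with optional z-standardization whose parameters come from the
training fold only) and predicts the held-out subject. The per-subject
correct/incorrect flags form the outcome vector that feeds the exact
paired binomial comparison of feature families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import FeatureMatrix
from .svm import SvmConfig, train_linear_svm

POSITIVE_CLASS = "patient"  # sensitivity = patient detection rate


@dataclass
class OutcomeVector:
    """Per-subject LOOCV results for one feature family."""

    subject_ids: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    family: str = ""

    def __post_init__(self):
        n = len(self.subject_ids)
        if not (len(self.true_labels) == len(self.predicted_labels) == n):
            raise ValueError("outcome vector fields differ in length")

    @property
    def correct(self) -> np.ndarray:
        """0/1 per subject: was the subject classified correctly?"""
        return np.array(
            [int(t == p) for t, p in zip(self.true_labels, self.predicted_labels)]
        )

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "group": self.true_labels,
                "predicted": self.predicted_labels,
                "correct": self.correct,
            }
        )


@dataclass
class ClassificationSummary:
    """Accuracy / sensitivity / specificity, patient = positive class."""

    accuracy: float
    sensitivity: float
    specificity: float
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n": self.n,
        }


def summarize(
    outcomes: OutcomeVector, positive_class: str = POSITIVE_CLASS
) -> ClassificationSummary:
    """Accuracy = (TP+TN)/n; sensitivity = TP/(TP+FN); specificity = TN/(TN+FP)."""
    if outcomes.n == 0:
        raise ValueError("empty outcome vector")
    true = np.asarray(outcomes.true_labels)
    corr = outcomes.correct.astype(bool)
    pos = true == positive_class
    acc = float(corr.mean())
    sens = float(corr[pos].mean()) if pos.any() else float("nan")
    spec = float(corr[~pos].mean()) if (~pos).any() else float("nan")
    return ClassificationSummary(accuracy=acc, sensitivity=sens, specificity=spec, n=outcomes.n)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv(
    features: FeatureMatrix, cfg: SvmConfig | None = None
) -> tuple[OutcomeVector, ClassificationSummary]:
    """Leave-one-out cross-validation of the linear SVM on one family.

    Standardization parameters, when enabled, are estimated on each
    training fold and applied to its held-out subject, so no information
    leaks from the test instance into training.
    """
    cfg = cfg or SvmConfig()
    X = features.values
    labels = np.asarray(features.group_labels)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two groups")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"group {c!r} has fewer than 2 members")
    # decision sign: positive class is the one sorted last by train_linear_svm
    pos_label = classes[1]

    predicted = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        X_tr, X_te = X[tr], X[~tr]
        y_tr = labels[tr]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i}: training set contains a single class")
        if cfg.standardize_in_fold:
            X_tr, X_te = _standardize(X_tr, X_te)
        model = train_linear_svm(X_tr, y_tr, cfg)
        pred = model.predict(X_te)[0]
        predicted.append(str(pos_label if pred > 0 else classes[0]))
    outcomes = OutcomeVector(
        subject_ids=list(features.subject_ids),
        true_labels=[str(x) for x in labels],
        predicted_labels=predicted,
        family=features.family,
    )
    return outcomes, summarize(outcomes)
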