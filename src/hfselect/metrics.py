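"""Scalar evaluation criteria for binary outcome classifiers.

Confusion counts, accuracy, PPV (precision), recall, F-score, Matthews
correlation coefficient (MCC) with its affine transfer to [0, 1], ROC
AUC, and the full six-criterion profile of a fitted random-forest
evaluation model.

With ~32% positive prevalence, accuracy and recall alone overstate
performance; MCC is carried as the imbalance-robust criterion and is
mapped to ``(mcc + 1) / 2`` wherever a [0, 1] scale is required for
comparison with the other criteria.

Zero-denominator conventions (degenerate predictions): PPV, recall and
F-score are defined as 0 with a warning; MCC is 0 when any factor of its
radicand vanishes.  These keep profiles total on degenerate splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .data import FeatureTable, ValidationError

__all__ = [
    "ConfusionCounts",
    "EvaluationProfile",
    "UndefinedAUCError",
    "confusion",
    "accuracy",
    "ppv",
    "recall",
    "f_score",
    "mcc",
    "normalize_mcc",
    "roc_auc",
    "evaluate_model",
]

AGGREGATION_MODES = ("support_weighted", "positive_class")
AUC_MODES = ("proba", "label")


class UndefinedAUCError(ValueError):
    """ROC AUC is undefined when only one class is present."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.N < 1:
            raise ValueError("need at least one observation")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def swapped(self) -> "ConfusionCounts":
        """Counts with the class labels exchanged."""
        return ConfusionCounts(TP=self.TN, TN=self.TP, FP=self.FN, FN=self.FP)


@dataclass(frozen=True)
class EvaluationProfile:
    """The six-criterion evaluation set attached to one method."""

    acc: float
    auc: float
    f_score: float
    mcc: float
    ppv: float
    recall: float
    aggregation_mode: str = "support_weighted"

    @property
    def mcc_normalized(self) -> float:
        return normalize_mcc(self.mcc)

    def as_row(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "mcc": self.mcc,
            "mcc_normalized": self.mcc_normalized,
            "f_score": self.f_score,
            "ppv": self.ppv,
            "recall": self.recall,
        }


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y, dtype=int)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    bad = set(np.unique(arr)) - {0, 1}
    if bad:
        raise ValueError(f"{name} must be 0/1, found {sorted(bad)}")
    return arr


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("need at least one observation")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has zero denominator; defined as 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return (c.TP + c.TN) / c.N


def ppv(c: ConfusionCounts) -> float:
    """Positive predictive value TP / (TP + FP)."""
    return _ratio(c.TP, c.TP + c.FP, "PPV")


def recall(c: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN)."""
    return _ratio(c.TP, c.TP + c.FN, "recall")


def f_score(c: ConfusionCounts) -> float:
    """Harmonic mean of PPV and recall."""
    p, r = ppv(c), recall(c)
    if p + r == 0:
        warnings.warn("F-score has zero denominator; defined as 0", stacklevel=2)
        return 0.0
    return 2 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; when any
    factor of the radicand is zero the coefficient is 0 by convention.
    """
    factors = (c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN)
    if 0 in factors:
        return 0.0
    num = c.TP * c.TN - c.FN * c.FP
    return num / float(np.sqrt(np.prod([float(f) for f in factors])))


def normalize_mcc(m: float) -> float:
    """Affine transfer of MCC from [-1, 1] to [0, 1]: ``(m + 1) / 2``."""
    if not -1.0 <= m <= 1.0:
        raise ValueError(f"MCC must lie in [-1,1], got {m}")
    return (m + 1.0) / 2.0


def roc_auc(y_true, scores) -> float:
    """Trapezoidal area under the ROC curve (ties counted one half).

    Equals the Mann-Whitney probability that a random positive outscores
    a random negative.
    """
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if len(np.unique(t)) < 2:
        raise UndefinedAUCError("ROC AUC needs both classes present")
    return float(roc_auc_score(t, s))


def _aggregate(c: ConfusionCounts, mode: str) -> tuple[float, float, float]:
    """(ppv, recall, f_score) under the requested aggregation."""
    if mode == "positive_class":
        return ppv(c), recall(c), f_score(c)
    if mode == "support_weighted":
        pos, neg = c, c.swapped()
        n1, n0 = c.TP + c.FN, c.TN + c.FP
        n = n1 + n0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ppv_w = (n1 * ppv(pos) + n0 * ppv(neg)) / n
            rec_w = (n1 * recall(pos) + n0 * recall(neg)) / n
            f_w = (n1 * f_score(pos) + n0 * f_score(neg)) / n
        return ppv_w, rec_w, f_w
    raise ValueError(f"unknown aggregation mode {mode!r}")


def evaluate_model(
    train: FeatureTable,
    test: FeatureTable,
    feature_subset,
    model_seed: int = 0,
    aggregation: str = "support_weighted",
    auc_mode: str = "proba",
    n_estimators: int = 100,
) -> EvaluationProfile:
    """Fit the evaluation model on a feature subset and profile it on test.

    The evaluation model is a random forest (bagged decision trees with
    majority vote for labels and mean leaf probability for scores),
    seeded for reproducibility.  ``auc_mode='proba'`` ranks by the
    class-1 probability; ``'label'`` computes the (single-threshold) ROC
    from hard predictions.
    """
    subset = tuple(sorted(int(j) for j in feature_subset))
    if not subset:
        raise ValidationError("feature subset must be nonempty")
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")
    if auc_mode not in AUC_MODES:
        raise ValueError(f"auc_mode must be one of {AUC_MODES}")
    train.require_evaluable()
    if test.has_missing():
        raise ValidationError("test table has missing values; impute first")

    model = RandomForestClassifier(n_estimators=n_estimators, random_state=model_seed)
    model.fit(train.values[:, subset], train.outcome)
    predicted = model.predict(test.values[:, subset])
    counts = confusion(test.outcome, predicted)
    if auc_mode == "proba":
        class_one = list(model.classes_).index(1)
        score_vec = model.predict_proba(test.values[:, subset])[:, class_one]
    else:
        score_vec = predicted.astype(float)
    p_agg, r_agg, f_agg = _aggregate(counts, aggregation)
    return EvaluationProfile(
        acc=accuracy(counts),
        auc=roc_auc(test.outcome, score_vec),
        f_score=f_agg,
        mcc=mcc(counts),
        ppv=p_agg,
        recall=r_agg,
        aggregation_mode=aggregation,
    )
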