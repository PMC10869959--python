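"""Filter and embedded pre-selectors: variance threshold, ANOVA-F k-best,
L1-penalized linear selection, and tree-importance selection.

These form the dimension-reduction stage that precedes the wrapper
search: each selector keeps a subset of the training columns, the
evaluation model is refit on that subset, and the resulting profile is
handed to the hesitant-fuzzy scoring stage to pick the winner.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .data import FeatureTable, ValidationError
from .metrics import EvaluationProfile, evaluate_model

__all__ = [
    "FilterConfig",
    "SelectionResult",
    "SelectionEmptyError",
    "anova_f",
    "select_variance_threshold",
    "select_kbest",
    "select_l1",
    "select_tree",
    "run_filter_stage",
    "FILTER_METHOD_IDS",
]

FILTER_METHOD_IDS = ("VT", "kBest", "L1", "Tree")


class SelectionEmptyError(ValueError):
    """A selector kept no features."""


class DegenerateFeatureError(ValueError):
    """The ANOVA F statistic is undefined (constant feature)."""


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the four pre-selectors.

    ``vt_threshold`` applies to raw (unstandardized) training variance —
    on standardized columns every variance is 1 and the threshold would
    be vacuous.  ``kbest_k`` defaults to 19 retained features;
    ``l1_strength`` is the inverse regularization of the L1 linear
    model; ``tree_importance_rule`` keeps features whose impurity
    importance exceeds the mean (or median / a quantile) importance.
    """

    vt_threshold: float = 0.35
    kbest_k: int = 19
    l1_strength: float = 1.0
    tree_importance_rule: str = "mean"
    seed: int = 0

    def validate(self, p: int, for_kbest: bool = False) -> None:
        if self.vt_threshold < 0:
            raise ValueError("vt_threshold must be >= 0")
        if for_kbest and not 1 <= self.kbest_k <= p:
            raise ValueError(f"kbest_k must be in [1, {p}], got {self.kbest_k}")
        if self.l1_strength <= 0:
            raise ValueError("l1_strength must be positive")


@dataclass(frozen=True)
class SelectionResult:
    """One selector's outcome: subset, evaluation profile, bookkeeping."""

    method_id: str
    selected: tuple[int, ...]
    profile: Optional[EvaluationProfile]
    runtime_s: float
    error: Optional[str] = None

    @property
    def nfs(self) -> int:
        return len(self.selected)

    def as_row(self) -> dict:
        row = {"method": self.method_id, "runtime_s": self.runtime_s, "nfs": self.nfs}
        if self.profile is not None:
            row.update(self.profile.as_row())
        if self.error is not None:
            row["error"] = self.error
        return row


def anova_f(feature, y) -> float:
    """One-way two-group ANOVA F statistic of a feature against the outcome.

    Between-group mean square over within-group mean square.  A constant
    nonzero between-group difference with zero within-group variance
    yields ``inf``; a fully constant feature is undefined.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = [x[y == 0], x[y == 1]]
    if any(g.size == 0 for g in groups):
        raise ValidationError("both classes need at least one value")
    n = x.size
    grand = x.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        if ssb == 0:
            raise DegenerateFeatureError("constant feature: F undefined")
        return float("inf")
    msb = ssb / (len(groups) - 1)
    msw = ssw / (n - len(groups))
    return float(msb / msw)


def select_variance_threshold(train: FeatureTable, cfg: FilterConfig) -> tuple[int, ...]:
    """Keep features whose training population variance exceeds the threshold."""
    cfg.validate(train.p)
    variances = np.var(train.values, axis=0, ddof=0)
    kept = tuple(int(j) for j in np.flatnonzero(variances > cfg.vt_threshold))
    if not kept:
        raise SelectionEmptyError(
            f"no feature has variance > {cfg.vt_threshold}"
        )
    return kept


def select_kbest(train: FeatureTable, cfg: FilterConfig) -> tuple[int, ...]:
    """Keep the k features with the largest ANOVA F against the outcome.

    Ties break toward the lower column index; features with undefined F
    rank last (with a warning).
    """
    cfg.validate(train.p, for_kbest=True)
    f_values = np.empty(train.p)
    for j in range(train.p):
        try:
            f_values[j] = anova_f(train.values[:, j], train.outcome)
        except DegenerateFeatureError:
            warnings.warn(
                f"feature {train.feature_names[j]!r} has undefined F; ranked last",
                stacklevel=2,
            )
            f_values[j] = -np.inf
    order = np.argsort(-f_values, kind="stable")  # stable: ties -> lower index
    return tuple(sorted(int(j) for j in order[: cfg.kbest_k]))


def select_l1(train: FeatureTable, cfg: FilterConfig, tol: float = 1e-10) -> tuple[int, ...]:
    """Keep features with nonzero coefficients of an L1-penalized
    logistic-loss linear classifier fitted on the (standardized) train set."""
    cfg.validate(train.p)
    model = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=cfg.l1_strength,
        solver="liblinear",
        random_state=cfg.seed,
        max_iter=1000,
    )
    model.fit(train.values, train.outcome)
    if model.n_iter_.max() >= 1000:
        raise RuntimeError(f"L1 solver did not converge in {int(model.n_iter_.max())} iterations")
    coef = np.abs(model.coef_.ravel())
    kept = tuple(int(j) for j in np.flatnonzero(coef > tol))
    if not kept:
        raise SelectionEmptyError("L1 penalty zeroed every coefficient")
    return kept


def select_tree(
    train: FeatureTable, cfg: FilterConfig, n_estimators: int = 100
) -> tuple[int, ...]:
    """Keep features whose forest impurity importance clears the rule
    threshold (default: the mean importance, i.e. 1/p when importances
    sum to one)."""
    cfg.validate(train.p)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=cfg.seed)
    forest.fit(train.values, train.outcome)
    importances = forest.feature_importances_
    rule = cfg.tree_importance_rule
    if rule == "mean":
        cut = importances.mean()
    elif rule == "median":
        cut = np.median(importances)
    elif rule.startswith("quantile:"):
        cut = np.quantile(importances, float(rule.split(":", 1)[1]))
    else:
        raise ValueError(f"unknown tree_importance_rule {rule!r}")
    kept = tuple(int(j) for j in np.flatnonzero(importances >= cut))
    if not kept:  # cannot happen with mean/median rules, but keep total
        raise SelectionEmptyError("no feature importance reached the threshold")
    return kept


_SELECTORS = {
    "VT": select_variance_threshold,
    "kBest": select_kbest,
    "L1": select_l1,
    "Tree": select_tree,
}


def run_filter_stage(
    train: FeatureTable,
    test: FeatureTable,
    cfg: FilterConfig,
    aggregation: str = "support_weighted",
    auc_mode: str = "proba",
    n_estimators: int = 100,
    raw_train: Optional[FeatureTable] = None,
) -> list[SelectionResult]:
    """Run all four pre-selectors and profile each subset on the test set.

    ``raw_train``, when given, supplies unstandardized columns for the
    variance threshold (whose default of 0.35 is meaningful only on the
    original scales).  Per-method failures become error rows; they do
    not abort the stage.
    """
    results: list[SelectionResult] = []
    for method_id in FILTER_METHOD_IDS:
        start = time.perf_counter()
        try:
            source = raw_train if (method_id == "VT" and raw_train is not None) else train
            selected = _SELECTORS[method_id](source, cfg)
            profile = evaluate_model(
                train,
                test,
                selected,
                model_seed=cfg.seed,
                aggregation=aggregation,
                auc_mode=auc_mode,
                n_estimators=n_estimators,
            )
            results.append(
                SelectionResult(
                    method_id=method_id,
                    selected=tuple(selected),
                    profile=profile,
                    runtime_s=time.perf_counter() - start,
                )
            )
        except Exception as exc:  # per-row failure, stage continues
            results.append(
                SelectionResult(
                    method_id=method_id,
                    selected=(),
                    profile=None,
                    runtime_s=time.perf_counter() - start,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results
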