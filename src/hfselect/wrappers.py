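"""Wrapper feature-subset search around a cross-validated random forest.

Implements sequential forward selection (SFS), sequential backward
selection (SBS), their floating variants (SFFS/SFBS, which conditionally
reverse earlier inclusions/exclusions when doing so strictly improves
the best score recorded at a subset size), and random subset search.
Every candidate subset is scored by stratified k-fold cross-validated
accuracy of the evaluation model; ties always break toward the lowest
feature index so a run is fully determined by (data, config, seeds).

Each step of a search is recorded as :class:`StepStats` — the mean fold
score plus spread statistics: ``std_dev`` is the population standard
deviation of the ``m`` fold scores, ``std_err = std_dev / sqrt(m - 1)``
(the sample-SD standard error of the mean), and ``ci_bound`` is
``std_err`` times the two-sided 95% Student-t quantile with ``m``
degrees of freedom.  These conventions match the trace layout of the
classic sequential-selector reports.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .data import FeatureTable, ValidationError
from .metrics import EvaluationProfile

__all__ = [
    "WrapperConfig",
    "StepStats",
    "WrapperTrace",
    "CVError",
    "cv_score",
    "make_step_stats",
    "sfs",
    "sbs",
    "sffs",
    "sfbs",
    "random_search",
    "run_wrapper",
    "WRAPPER_ALGORITHMS",
]

WRAPPER_ALGORITHMS = ("SFS", "SBS", "SFFS", "SFBS", "RandomSearch")


class CVError(ValueError):
    """A cross-validation fold is degenerate."""


@dataclass(frozen=True)
class WrapperConfig:
    """Search and cross-validation settings for the wrapper stage."""

    target_k: int = 7
    algorithm: str = "SFS"
    cv_folds: int = 10
    cv_seed: int = 0
    model_seed: int = 0
    search_seed: int = 0
    random_search_iters: int = 200
    scoring: str = "accuracy"
    n_estimators: int = 100

    def validate(self, pool_size: int, check_target_k: bool = True) -> None:
        if check_target_k and not 1 <= self.target_k <= pool_size:
            raise ValueError(f"target_k must be in [1, {pool_size}]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.algorithm not in WRAPPER_ALGORITHMS:
            raise ValueError(f"algorithm must be one of {WRAPPER_ALGORITHMS}")
        if self.scoring != "accuracy":
            raise ValueError("only accuracy scoring is supported")


@dataclass(frozen=True)
class StepStats:
    """Cross-validation statistics of one recorded subset."""

    step_index: int
    feature_idx: tuple[int, ...]
    feature_names: tuple[str, ...]
    avg_score: float
    std_dev: float
    std_err: float
    ci_bound: float


@dataclass(frozen=True)
class WrapperTrace:
    """Full record of one wrapper run."""

    algorithm: str
    steps: tuple[StepStats, ...]
    final_subset: tuple[int, ...]
    runtime_s: float
    final_profile: Optional[EvaluationProfile] = None

    def with_profile(self, profile: EvaluationProfile) -> "WrapperTrace":
        return replace(self, final_profile=profile)


def cv_score(
    train: FeatureTable, subset: Sequence[int], cfg: WrapperConfig
) -> tuple[float, np.ndarray]:
    """Mean and per-fold accuracy of the evaluation model on a subset."""
    subset = tuple(sorted(int(j) for j in subset))
    if not subset:
        raise ValidationError("subset must be nonempty")
    train.require_evaluable()
    X = train.values[:, subset]
    y = train.outcome
    folds = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.cv_seed
    )
    scores = np.empty(cfg.cv_folds)
    for i, (fit_idx, val_idx) in enumerate(folds.split(X, y)):
        if len(np.unique(y[fit_idx])) < 2:
            raise CVError(f"fold {i} has a single outcome class in its training part")
        model = RandomForestClassifier(
            n_estimators=cfg.n_estimators, random_state=cfg.model_seed
        )
        model.fit(X[fit_idx], y[fit_idx])
        scores[i] = float(np.mean(model.predict(X[val_idx]) == y[val_idx]))
    return float(scores.mean()), scores


def make_step_stats(
    fold_scores: Sequence[float],
    subset: Sequence[int],
    names: Sequence[str],
    step_index: int = 0,
) -> StepStats:
    scores = np.asarray(fold_scores, dtype=float)
    m = scores.size
    if m < 2:
        raise ValueError("need at least two fold scores")
    std_dev = float(scores.std(ddof=0))
    std_err = std_dev / np.sqrt(m - 1)
    ci_bound = std_err * float(stats.t.ppf(0.975, df=m))
    return StepStats(
        step_index=step_index,
        feature_idx=tuple(int(j) for j in subset),
        feature_names=tuple(names),
        avg_score=float(scores.mean()),
        std_dev=std_dev,
        std_err=std_err,
        ci_bound=ci_bound,
    )


class _SubsetScorer:
    """Memoized CV scoring of subsets within one search run."""

    def __init__(self, train: FeatureTable, cfg: WrapperConfig):
        self.train = train
        self.cfg = cfg
        self._cache: dict[tuple[int, ...], tuple[float, np.ndarray]] = {}

    def __call__(self, subset: Sequence[int]) -> tuple[float, np.ndarray]:
        key = tuple(sorted(int(j) for j in subset))
        if key not in self._cache:
            self._cache[key] = cv_score(self.train, key, self.cfg)
        return self._cache[key]


def _best_candidate(scorer, base: set[int], candidates: Sequence[int], adding: bool):
    """Candidate whose add/remove maximizes the CV mean; ties -> lowest index."""
    best = None
    for cand in sorted(candidates):
        trial = base | {cand} if adding else base - {cand}
        mean, folds = scorer(trial)
        if best is None or mean > best[1]:
            best = (cand, mean, folds, tuple(sorted(trial)))
    return best


def _steps_from_best(best_at_size, names, sizes) -> tuple[StepStats, ...]:
    steps = []
    for i, size in enumerate(sizes):
        mean, folds, subset = best_at_size[size]
        steps.append(
            make_step_stats(folds, subset, [names[j] for j in subset], step_index=i)
        )
    return tuple(steps)


def sfs(train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig) -> WrapperTrace:
    """Greedy forward selection up to ``target_k`` features."""
    start = time.perf_counter()
    pool = tuple(sorted(set(int(j) for j in pool)))
    cfg.validate(len(pool))
    scorer = _SubsetScorer(train, cfg)
    current: set[int] = set()
    best_at_size: dict[int, tuple[float, np.ndarray, tuple[int, ...]]] = {}
    while len(current) < cfg.target_k:
        cand, mean, folds, subset = _best_candidate(
            scorer, current, [j for j in pool if j not in current], adding=True
        )
        current.add(cand)
        best_at_size[len(current)] = (mean, folds, subset)
    steps = _steps_from_best(best_at_size, train.feature_names, range(1, cfg.target_k + 1))
    return WrapperTrace(
        "SFS", steps, tuple(sorted(current)), time.perf_counter() - start
    )


def sbs(train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig) -> WrapperTrace:
    """Greedy backward elimination down to ``target_k`` features."""
    start = time.perf_counter()
    pool = tuple(sorted(set(int(j) for j in pool)))
    cfg.validate(len(pool))
    scorer = _SubsetScorer(train, cfg)
    current = set(pool)
    best_at_size = {}
    mean, folds = scorer(current)
    best_at_size[len(current)] = (mean, folds, tuple(sorted(current)))
    while len(current) > cfg.target_k:
        cand, mean, folds, subset = _best_candidate(
            scorer, current, sorted(current), adding=False
        )
        current.remove(cand)
        best_at_size[len(current)] = (mean, folds, subset)
    sizes = range(len(pool), cfg.target_k - 1, -1)
    steps = _steps_from_best(best_at_size, train.feature_names, sizes)
    return WrapperTrace(
        "SBS", steps, tuple(sorted(current)), time.perf_counter() - start
    )


def _update_best(best_at_size, size, mean, folds, subset) -> bool:
    """Record subset as best at its size if strictly better (or first)."""
    if size not in best_at_size or mean > best_at_size[size][0]:
        best_at_size[size] = (mean, folds, subset)
        return True
    return False


def sffs(train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig) -> WrapperTrace:
    """Floating forward selection.

    After each inclusion, conditionally excludes features while the
    exclusion strictly improves the best recorded score at the smaller
    size; strict-improvement bookkeeping guarantees termination.  The
    sweep continues through the whole pool (subset sizes float up and
    down along the way) and the best subset of size ``target_k``
    encountered anywhere in the sweep is returned — this is what lets
    the floating variant recover feature pairs that are informative
    only jointly, which a greedy forward pass stopped at ``target_k``
    can miss.
    """
    start = time.perf_counter()
    pool = tuple(sorted(set(int(j) for j in pool)))
    cfg.validate(len(pool))
    scorer = _SubsetScorer(train, cfg)
    current: set[int] = set()
    best_at_size: dict[int, tuple[float, np.ndarray, tuple[int, ...]]] = {}
    while len(current) < len(pool):
        cand, mean, folds, subset = _best_candidate(
            scorer, current, [j for j in pool if j not in current], adding=True
        )
        current.add(cand)
        _update_best(best_at_size, len(current), mean, folds, subset)
        # conditional exclusion
        while len(current) > 2:
            worst = _best_candidate(scorer, current, sorted(current), adding=False)
            cand_r, mean_r, folds_r, subset_r = worst
            if mean_r > best_at_size.get(len(current) - 1, (-np.inf,))[0]:
                current.remove(cand_r)
                _update_best(best_at_size, len(current), mean_r, folds_r, subset_r)
            else:
                break
    final = best_at_size[cfg.target_k][2]
    steps = _steps_from_best(best_at_size, train.feature_names, range(1, cfg.target_k + 1))
    return WrapperTrace("SFFS", steps, final, time.perf_counter() - start)


def sfbs(train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig) -> WrapperTrace:
    """Floating backward selection (mirror image of :func:`sffs`): the
    sweep continues down to single features, with conditional
    re-inclusions, and the best subset of size ``target_k`` encountered
    is returned."""
    start = time.perf_counter()
    pool = tuple(sorted(set(int(j) for j in pool)))
    cfg.validate(len(pool))
    scorer = _SubsetScorer(train, cfg)
    current = set(pool)
    best_at_size = {}
    mean, folds = scorer(current)
    best_at_size[len(current)] = (mean, folds, tuple(sorted(current)))
    while len(current) > 1:
        cand, mean, folds, subset = _best_candidate(
            scorer, current, sorted(current), adding=False
        )
        current.remove(cand)
        _update_best(best_at_size, len(current), mean, folds, subset)
        # conditional inclusion
        while len(current) < len(pool) - 1:
            best_add = _best_candidate(
                scorer, current, [j for j in pool if j not in current], adding=True
            )
            cand_a, mean_a, folds_a, subset_a = best_add
            if mean_a > best_at_size.get(len(current) + 1, (-np.inf,))[0]:
                current.add(cand_a)
                _update_best(best_at_size, len(current), mean_a, folds_a, subset_a)
            else:
                break
    final = best_at_size[cfg.target_k][2]
    sizes = range(len(pool), cfg.target_k - 1, -1)
    steps = _steps_from_best(best_at_size, train.feature_names, sizes)
    return WrapperTrace("SFBS", steps, final, time.perf_counter() - start)


def random_search(
    train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig
) -> WrapperTrace:
    """Random subset search: samples subsets (size uniform on
    ``[1, |pool|]``) and keeps the best by CV mean accuracy.  Unlike the
    sequential searches it is not constrained to ``target_k``: it
    reports its best subset at whatever size that subset has."""
    start = time.perf_counter()
    pool = tuple(sorted(set(int(j) for j in pool)))
    cfg.validate(len(pool), check_target_k=False)
    if cfg.random_search_iters < 1:
        raise ValueError("random_search_iters must be >= 1")
    rng = np.random.default_rng(cfg.search_seed)
    scorer = _SubsetScorer(train, cfg)
    best: Optional[tuple[float, np.ndarray, tuple[int, ...]]] = None
    steps: list[StepStats] = []
    for it in range(cfg.random_search_iters):
        size = int(rng.integers(1, len(pool) + 1))
        subset = tuple(sorted(int(j) for j in rng.choice(pool, size=size, replace=False)))
        mean, folds = scorer(subset)
        if best is None or mean > best[0]:
            best = (mean, folds, subset)
            steps.append(
                make_step_stats(
                    folds,
                    subset,
                    [train.feature_names[j] for j in subset],
                    step_index=it,
                )
            )
    return WrapperTrace(
        "RandomSearch", tuple(steps), best[2], time.perf_counter() - start
    )


_ALGORITHMS = {
    "SFS": sfs,
    "SBS": sbs,
    "SFFS": sffs,
    "SFBS": sfbs,
    "RandomSearch": random_search,
}


def run_wrapper(
    train: FeatureTable, pool: Sequence[int], cfg: WrapperConfig
) -> WrapperTrace:
    """Dispatch to the configured wrapper algorithm."""
    return _ALGORITHMS[cfg.algorithm](train, pool, replace(cfg, algorithm=cfg.algorithm))
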