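"""End-to-end orchestration of the five-step hybrid selection method.

Step 1 splits the cohort 80/20 (stratified); step 2 runs the four
filter/embedded pre-selectors on the preprocessed training partition
and profiles each on the held-out test rows; step 3 ranks the four
methods with the hesitant-fuzzy score and picks the winner (and
runner-up); step 4 runs each configured wrapper algorithm over the
winner's feature pool with cross-validated accuracy as the greedy
criterion; step 5 refits on the full training partition and profiles
every final subset on the held-out test rows, alongside the per-step
CV traces.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .data import (
    DataSplit,
    FeatureTable,
    impute_median,
    split_train_test,
    standardize,
)
from .filters import FilterConfig, SelectionResult, run_filter_stage
from .hfs import MethodScore, score_selection_results
from .metrics import evaluate_model
from .wrappers import (
    WRAPPER_ALGORITHMS,
    WrapperConfig,
    WrapperTrace,
    run_wrapper,
)

__all__ = [
    "PipelineConfig",
    "HybridRunReport",
    "ArmComparison",
    "run_hybrid",
    "compare_arms",
    "write_report",
    "prepare_partitions",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one hybrid run; seeds can derive from one master seed."""

    test_fraction: float = 0.2
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    wrapper_cfg: WrapperConfig = field(default_factory=WrapperConfig)
    wrapper_algorithms: tuple[str, ...] = WRAPPER_ALGORITHMS
    aggregation: str = "support_weighted"
    auc_mode: str = "proba"
    table_fidelity_rounding: bool = False
    split_seed: int = 0
    eval_n_estimators: int = 100

    @classmethod
    def from_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Derive all component seeds deterministically from one integer."""
        ss = np.random.SeedSequence(seed)
        split_s, filt_s, cv_s, model_s, search_s = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
        )
        cfg = cls(
            split_seed=split_s,
            filter_cfg=FilterConfig(seed=filt_s),
            wrapper_cfg=WrapperConfig(
                cv_seed=cv_s, model_seed=model_s, search_seed=search_s
            ),
        )
        return replace(cfg, **overrides) if overrides else cfg

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class HybridRunReport:
    """Everything one hybrid run produces, table-shaped."""

    filter_results: tuple[SelectionResult, ...]
    hfs_scores: tuple[MethodScore, ...]
    winner: str
    runner_up: Optional[str]
    hybrid_results: tuple[SelectionResult, ...]
    traces: dict[str, WrapperTrace]
    best_hybrid: str
    chosen_features: tuple[str, ...]
    chosen_indices: tuple[int, ...]
    split: DataSplit
    config: PipelineConfig
    runtime_s: float


@dataclass(frozen=True)
class ArmComparison:
    """Wrapper-alone vs winner-pool vs runner-up-pool, same split/seeds."""

    arms: tuple[SelectionResult, ...]
    winner: str
    runner_up: Optional[str]


def prepare_partitions(
    data: FeatureTable, test_fraction: float, split_seed: int
) -> tuple[FeatureTable, FeatureTable, FeatureTable, DataSplit]:
    """Split, impute and standardize; returns (train, test, raw_train, split).

    ``raw_train`` is imputed but unstandardized — the variance-threshold
    selector needs original scales.
    """
    split = split_train_test(data, test_fraction, split_seed, stratified=True)
    imputed = impute_median(data, split) if data.has_missing() else data
    scaled = standardize(imputed, split)
    train = scaled.subset_rows(split.train_indices)
    test = scaled.subset_rows(split.test_indices)
    raw_train = imputed.subset_rows(split.train_indices)
    return train, test, raw_train, split


def _evaluate_subset(train, test, subset, cfg: PipelineConfig):
    return evaluate_model(
        train,
        test,
        subset,
        model_seed=cfg.wrapper_cfg.model_seed,
        aggregation=cfg.aggregation,
        auc_mode=cfg.auc_mode,
        n_estimators=cfg.eval_n_estimators,
    )


def _pick_stage4_methods(
    scores: Sequence[MethodScore],
    filter_results: Sequence[SelectionResult],
    target_k: int,
) -> tuple[str, Optional[str], tuple[int, ...]]:
    """Winner and runner-up for the wrapper stage.

    The wrapper search needs a candidate pool of at least ``target_k``
    features, so the stage-4 winner is the highest-scoring method whose
    pool is large enough (the reported HFS ranking itself is untouched).
    If no method qualifies, the top-ranked method is used as-is and the
    search target shrinks to its pool size.
    """
    pools = {r.method_id: r.selected for r in filter_results if r.profile is not None}
    eligible = [s.method_id for s in scores if len(pools[s.method_id]) >= target_k]
    if eligible:
        winner = eligible[0]
        runner_up = eligible[1] if len(eligible) > 1 else None
    else:
        winner = scores[0].method_id
        runner_up = scores[1].method_id if len(scores) > 1 else None
    return winner, runner_up, pools[winner]


def run_hybrid(data: FeatureTable, cfg: PipelineConfig) -> HybridRunReport:
    """Run the full five-step hybrid selection method on one cohort."""
    t0 = time.perf_counter()
    train, test, raw_train, split = prepare_partitions(
        data, cfg.test_fraction, cfg.split_seed
    )

    filter_results = run_filter_stage(
        train,
        test,
        cfg.filter_cfg,
        aggregation=cfg.aggregation,
        auc_mode=cfg.auc_mode,
        n_estimators=cfg.eval_n_estimators,
        raw_train=raw_train,
    )
    scores = score_selection_results(
        filter_results, table_fidelity_rounding=cfg.table_fidelity_rounding
    )
    winner, runner_up, pool = _pick_stage4_methods(
        scores, filter_results, cfg.wrapper_cfg.target_k
    )
    effective_k = min(cfg.wrapper_cfg.target_k, len(pool))

    hybrid_results: list[SelectionResult] = []
    traces: dict[str, WrapperTrace] = {}
    for algorithm in cfg.wrapper_algorithms:
        wcfg = replace(cfg.wrapper_cfg, algorithm=algorithm, target_k=effective_k)
        start = time.perf_counter()
        trace = run_wrapper(train, pool, wcfg)
        profile = _evaluate_subset(train, test, trace.final_subset, cfg)
        trace = trace.with_profile(profile)
        traces[algorithm] = trace
        hybrid_results.append(
            SelectionResult(
                method_id=f"{winner}+{algorithm}",
                selected=trace.final_subset,
                profile=profile,
                runtime_s=time.perf_counter() - start,
            )
        )

    # best hybrid arm by held-out accuracy; ties by algorithm order
    best = max(hybrid_results, key=lambda r: r.profile.acc)
    best_alg = best.method_id.split("+", 1)[1]
    chosen_idx = best.selected
    chosen_names = tuple(data.feature_names[j] for j in chosen_idx)

    return HybridRunReport(
        filter_results=tuple(filter_results),
        hfs_scores=tuple(scores),
        winner=winner,
        runner_up=runner_up,
        hybrid_results=tuple(hybrid_results),
        traces=traces,
        best_hybrid=best_alg,
        chosen_features=chosen_names,
        chosen_indices=chosen_idx,
        split=split,
        config=cfg,
        runtime_s=time.perf_counter() - t0,
    )


def compare_arms(data: FeatureTable, cfg: PipelineConfig) -> ArmComparison:
    """Three controlled arms sharing one split and one set of seeds:
    the wrapper alone on all features, the wrapper on the HFS winner's
    pool, and the wrapper on the runner-up's pool."""
    train, test, raw_train, split = prepare_partitions(
        data, cfg.test_fraction, cfg.split_seed
    )
    filter_results = run_filter_stage(
        train,
        test,
        cfg.filter_cfg,
        aggregation=cfg.aggregation,
        auc_mode=cfg.auc_mode,
        n_estimators=cfg.eval_n_estimators,
        raw_train=raw_train,
    )
    scores = score_selection_results(
        filter_results, table_fidelity_rounding=cfg.table_fidelity_rounding
    )
    winner, runner_up, _ = _pick_stage4_methods(
        scores, filter_results, cfg.wrapper_cfg.target_k
    )
    algorithm = cfg.wrapper_cfg.algorithm

    pools = {f"{algorithm}-alone": tuple(range(data.p))}
    for method in (winner, runner_up):
        if method is not None:
            pool = next(r.selected for r in filter_results if r.method_id == method)
            pools[f"{method}+{algorithm}"] = pool

    arms = []
    for arm_id, pool in pools.items():
        start = time.perf_counter()
        wcfg = replace(
            cfg.wrapper_cfg,
            target_k=min(cfg.wrapper_cfg.target_k, len(pool)),
        )
        trace = run_wrapper(train, pool, wcfg)
        profile = _evaluate_subset(train, test, trace.final_subset, cfg)
        arms.append(
            SelectionResult(
                method_id=arm_id,
                selected=trace.final_subset,
                profile=profile,
                runtime_s=time.perf_counter() - start,
            )
        )
    return ArmComparison(arms=tuple(arms), winner=winner, runner_up=runner_up)


# ---------------------------------------------------------------------------
# report serialization

_PROFILE_COLUMNS = ["acc", "auc", "mcc", "mcc_normalized", "f_score", "ppv", "recall"]


def _results_frame(results: Sequence[SelectionResult], include_runtime: bool) -> pd.DataFrame:
    rows = [r.as_row() for r in results]
    frame = pd.DataFrame(rows)
    columns = ["method", "nfs"] + _PROFILE_COLUMNS
    if include_runtime:
        columns.insert(1, "runtime_s")
    if "error" in frame.columns:
        columns.append("error")
    return frame.reindex(columns=columns)


def _trace_frame(trace: WrapperTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "avg_score": [s.avg_score for s in trace.steps],
            "ci_bound": [s.ci_bound for s in trace.steps],
            "feature_idx": [str(s.feature_idx) for s in trace.steps],
            "feature_names": [str(s.feature_names) for s in trace.steps],
            "std_dev": [s.std_dev for s in trace.steps],
            "std_err": [s.std_err for s in trace.steps],
        }
    )


def write_report(
    report: HybridRunReport, outdir: str | Path, include_runtime: bool = True
) -> dict[str, Path]:
    """Write all report tables; returns the paths written.

    Runtimes are wall-clock and vary between runs; pass
    ``include_runtime=False`` for byte-reproducible tables (runtimes
    then appear only in the manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["filter_stage"] = outdir / "filter_stage.csv"
    _results_frame(report.filter_results, include_runtime).to_csv(
        paths["filter_stage"], index=False
    )

    paths["hfs_scores"] = outdir / "hfs_scores.csv"
    pd.DataFrame(
        [
            {"method": s.method_id, "deviation": s.deviation, "score": s.score}
            for s in report.hfs_scores
        ]
    ).to_csv(paths["hfs_scores"], index=False)

    paths["hybrid_stage"] = outdir / "hybrid_stage.csv"
    _results_frame(report.hybrid_results, include_runtime).to_csv(
        paths["hybrid_stage"], index=False
    )

    paths["best_trace"] = outdir / "best_trace.csv"
    _trace_frame(report.traces[report.best_hybrid]).to_csv(
        paths["best_trace"], index=False
    )

    paths["chosen_features"] = outdir / "chosen_features.json"
    paths["chosen_features"].write_text(
        json.dumps(
            {
                "winner": report.winner,
                "runner_up": report.runner_up,
                "best_hybrid": f"{report.winner}+{report.best_hybrid}",
                "feature_indices": list(report.chosen_indices),
                "feature_names": list(report.chosen_features),
            },
            indent=2,
        )
    )

    manifest = {
        "package": "hfselect",
        "version": _version,
        "config": report.config.as_dict(),
        "winner": report.winner,
        "runner_up": report.runner_up,
        "best_hybrid": report.best_hybrid,
        "runtime_s": report.runtime_s if include_runtime else None,
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
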