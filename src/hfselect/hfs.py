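"""Hesitant-fuzzy-set scoring of competing feature-selection methods.

Each method is summarized by a hesitant fuzzy element: the multiset of
its six evaluation criteria on the [0, 1] scale — accuracy, AUC,
F-score, normalized MCC, PPV and recall.  The *deviation degree* of an
element with values ``g_1..g_l`` is

    dev(h) = (1/l) * sqrt( sum over all ordered pairs (g_i - g_j)^2 )

i.e. the pairwise spread of the criteria (algebraically, sqrt(2) times
their population standard deviation).  The *score function* is its
reciprocal, ``SF(h) = 1 / dev(h)``: a method whose criteria agree
closely ranks higher than one whose criteria scatter.  The method with
the largest SF wins the pre-selection stage; the runner-up is kept for
comparison arms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .filters import SelectionResult
from .metrics import EvaluationProfile

__all__ = [
    "HesitantFuzzyElement",
    "MethodScore",
    "build_hfs",
    "deviation_degree",
    "score_function",
    "rank_methods",
    "score_selection_results",
]


@dataclass(frozen=True)
class HesitantFuzzyElement:
    """A method id with the multiset of its criterion values in [0, 1]."""

    method_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"criterion value {v} outside [0,1]")

    @property
    def l_h(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MethodScore:
    method_id: str
    deviation: float
    score: float


def build_hfs(profile: EvaluationProfile, method_id: str) -> HesitantFuzzyElement:
    """Six-criterion element of a profile; MCC enters in normalized form."""
    return HesitantFuzzyElement(
        method_id=method_id,
        values=(
            profile.acc,
            profile.auc,
            profile.f_score,
            profile.mcc_normalized,
            profile.ppv,
            profile.recall,
        ),
    )


def deviation_degree(h: HesitantFuzzyElement) -> float:
    """Pairwise spread of the element's criterion values (see module docs)."""
    if h.l_h < 2:
        raise ValueError("deviation degree needs at least two values")
    v = np.asarray(h.values)
    pair_sq = (v[:, None] - v[None, :]) ** 2  # all ordered pairs, diag 0
    return float(np.sqrt(pair_sq.sum()) / h.l_h)


def score_function(h: HesitantFuzzyElement) -> MethodScore:
    """Reciprocal deviation degree; an all-equal element scores +inf."""
    dev = deviation_degree(h)
    if dev == 0.0:
        warnings.warn(
            f"method {h.method_id!r} has identical criteria; score is +inf",
            stacklevel=2,
        )
        return MethodScore(h.method_id, 0.0, math.inf)
    return MethodScore(h.method_id, dev, 1.0 / dev)


def rank_methods(scores: Sequence[MethodScore]) -> list[MethodScore]:
    """Descending by score, ties by method id; winner first."""
    if not scores:
        raise ValueError("no method scores to rank")
    return sorted(scores, key=lambda s: (-s.score, s.method_id))


def _round_profile_values(values: tuple[float, ...], decimals: int) -> tuple[float, ...]:
    return tuple(round(v, decimals) for v in values)


def score_selection_results(
    results: Iterable[SelectionResult],
    table_fidelity_rounding: bool = False,
    fidelity_decimals: int = 2,
) -> list[MethodScore]:
    """Score every successful selector result and rank them.

    ``table_fidelity_rounding`` first rounds each criterion to the
    precision at which report tables display them, matching workflows
    that score the displayed rather than the full-precision values.
    """
    elements = []
    for res in results:
        if res.profile is None:
            continue
        h = build_hfs(res.profile, res.method_id)
        if table_fidelity_rounding:
            h = HesitantFuzzyElement(
                h.method_id, _round_profile_values(h.values, fidelity_decimals)
            )
        elements.append(h)
    return rank_methods([score_function(h) for h in elements])
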