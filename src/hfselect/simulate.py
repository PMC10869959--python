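"""Synthetic IVF/ICSI-like cohort generator with planted signal.

The real multi-center cohort behind this method is not publicly
deposited, so the generator emulates its summary shape: ~1000 treatment
cycles, 38 predictors, ~31.7% clinical pregnancy rate, and a designated
subset of 7 informative predictors (FSH dose, female age, oocyte count,
embryo-development counts, transferred-embryo quality grade, and the
number of previous unsuccessful cycles) carrying standardized
between-class mean shifts.  All other columns are outcome-independent
noise.

The outcome is drawn first (Bernoulli at the configured prevalence) and
features are generated conditional on class, which makes the planted
effect sizes exact by construction.  Count-like clinical variables are
Poisson; continuous ones are Gaussian around clinically plausible means
(female age ~30.9 yr, day-3 FSH dose ~10-13 mIU/ml).  All planted
directions are adverse: higher FSH dose, age, prior failures and the
embryo-count/grade variables are associated with a lower success
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable, write_cohort  # re-exported for convenience

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "write_cohort"]

DEFAULT_INFORMATIVE = ("FSH", "FAge", "oocytes", "16Cells", "compact", "GIII", "unsuccessful")
#: signed standardized mean shifts (class 1 minus class 0), magnitudes 0.4-0.8
DEFAULT_EFFECTS = (-0.8, -0.7, -0.5, -0.5, -0.4, -0.4, -0.6)

# (kind, base) per known clinical variable: Gaussian (base mean, sd) or
# Poisson (base rate); unknown informative names fall back to Gaussian(0,1).
_FEATURE_MODELS = {
    "FSH": ("normal", 10.5, 3.2),
    "FAge": ("normal", 30.9, 4.8),
    "oocytes": ("poisson", 9.0, None),
    "16Cells": ("poisson", 4.0, None),
    "compact": ("poisson", 3.0, None),
    "GIII": ("poisson", 1.5, None),
    "unsuccessful": ("poisson", 0.9, None),
}


class ConfigurationError(ValueError):
    """The cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 1000
    p: int = 38
    prevalence: float = 0.317
    informative_names: tuple[str, ...] = DEFAULT_INFORMATIVE
    effect_sizes: tuple[float, ...] = DEFAULT_EFFECTS
    noise_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0,1)")
        if len(self.informative_names) > self.p:
            raise ConfigurationError("more informative features than columns")
        if len(self.effect_sizes) != len(self.informative_names):
            raise ConfigurationError("one effect size per informative feature")
        if not all(np.isfinite(self.effect_sizes)):
            raise ConfigurationError("effect sizes must be finite")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise ConfigurationError("noise_correlation must be in [0,1)")


@dataclass(frozen=True)
class GroundTruth:
    """Which columns carry planted signal, and in which direction."""

    informative_indices: tuple[int, ...]
    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.informative_indices)) != len(self.informative_indices):
            raise ConfigurationError("informative indices must be unique")


# Layout mirrors the positions at which the clinical variables appear in
# the source cohort's column ordering (informative columns interleaved
# with noise), so selected-index tuples read naturally.
_PREFERRED_SLOTS = (1, 3, 6, 8, 11, 14, 17)


def _informative_slots(spec: CohortSpec) -> tuple[int, ...]:
    k = len(spec.informative_names)
    if k <= len(_PREFERRED_SLOTS) and spec.p > max(_PREFERRED_SLOTS[:k], default=-1):
        return _PREFERRED_SLOTS[:k]
    return tuple(range(k))


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort; deterministic given ``spec`` (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outcome = rng.binomial(1, spec.prevalence, size=spec.n)

    slots = _informative_slots(spec)
    names: list[str] = [f"x{j:02d}" for j in range(spec.p)]
    for slot, name in zip(slots, spec.informative_names):
        names[slot] = name

    values = np.empty((spec.n, spec.p), dtype=float)
    effect_of = dict(zip(slots, spec.effect_sizes))
    rho = spec.noise_correlation
    common = rng.standard_normal(spec.n) if rho > 0 else None

    for j in range(spec.p):
        if j in effect_of:
            name = names[j]
            kind, base, sd = _FEATURE_MODELS.get(name, ("normal", 0.0, 1.0))
            d = effect_of[j]
            if kind == "normal":
                # class-conditional means split by d standard deviations
                mu = base + np.where(outcome == 1, +d / 2, -d / 2) * sd
                values[:, j] = rng.normal(mu, sd)
            else:
                unit = np.sqrt(base)  # Poisson SD at the base rate
                lam = np.clip(base + np.where(outcome == 1, +d / 2, -d / 2) * unit, 0.05, None)
                values[:, j] = rng.poisson(lam)
        else:
            z = rng.standard_normal(spec.n)
            if common is not None:
                z = np.sqrt(rho) * common + np.sqrt(1 - rho) * z
            values[:, j] = z

    table = FeatureTable(values, tuple(names), outcome)
    truth = GroundTruth(
        informative_indices=slots,
        directions=tuple(int(np.sign(d)) if d else 0 for d in spec.effect_sizes),
    )
    return table, truth
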