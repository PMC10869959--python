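import dataclasses

import numpy as np
import pytest

from hfselect import CohortSpec, FeatureTable, PipelineConfig, generate_cohort
from hfselect.filters import FilterConfig
from hfselect.wrappers import WrapperConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default synthetic cohort (n=1000, p=38)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort for fast model-fitting tests."""
    return generate_cohort(CohortSpec(n=300, p=12, seed=5))


@pytest.fixture
def tiny_table():
    """Hand-built 6-row table with one perfectly separating feature."""
    rng = np.random.default_rng(0)
    n = 40
    outcome = np.repeat([0, 1], n // 2)
    values = np.column_stack(
        [
            outcome * 2.0 - 1.0 + rng.normal(0, 0.1, n),  # near-perfect
            rng.normal(size=n),
            rng.normal(size=n),
            rng.normal(size=n),
        ]
    )
    return FeatureTable(values, ("sig", "n1", "n2", "n3"), outcome)


def fast_pipeline_config(seed: int, **overrides) -> PipelineConfig:
    """Scaled-down pipeline settings used by the heavier end-to-end tests:
    SFS arm only, 3 CV folds, 15-tree CV forests, 50-tree evaluation forest."""
    cfg = PipelineConfig.from_seed(seed)
    cfg = dataclasses.replace(
        cfg,
        wrapper_cfg=dataclasses.replace(
            cfg.wrapper_cfg, cv_folds=3, n_estimators=15, random_search_iters=30
        ),
        wrapper_algorithms=("SFS",),
        eval_n_estimators=50,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def fast_wrapper_config(**overrides) -> WrapperConfig:
    base = WrapperConfig(cv_folds=3, n_estimators=15, random_search_iters=30)
    return dataclasses.replace(base, **overrides)
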