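from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from hfselect import (
    CohortSpec,
    FeatureTable,
    cv_score,
    generate_cohort,
    make_step_stats,
    random_search,
    sbs,
    sffs,
    sfbs,
    sfs,
)
from hfselect.wrappers import WrapperConfig

from conftest import fast_wrapper_config


def random_small_table(seed: int, n: int = 60, p: int = 6) -> FeatureTable:
    """Small table with a couple of weakly informative columns."""
    rng = np.random.default_rng(seed)
    outcome = rng.integers(0, 2, n)
    values = rng.normal(size=(n, p))
    values[:, 0] += 0.8 * outcome
    values[:, 2] += 0.5 * outcome
    return FeatureTable(values, tuple(f"f{j}" for j in range(p)), outcome)


def exhaustive_best(train, pool, size, cfg):
    """Enumerate all subsets of the given size; best mean, ties -> first
    in lexicographic order (matching the lowest-index tie rule)."""
    best = None
    for subset in combinations(sorted(pool), size):
        mean, _ = cv_score(train, subset, cfg)
        if best is None or mean > best[0]:
            best = (mean, subset)
    return best


class TestCvScore:
    def test_deterministic(self, tiny_table):
        cfg = fast_wrapper_config()
        m1, f1 = cv_score(tiny_table, (0, 1), cfg)
        m2, f2 = cv_score(tiny_table, (0, 1), cfg)
        assert m1 == m2
        np.testing.assert_array_equal(f1, f2)

    def test_constant_feature_scores_near_majority_rate(self):
        rng = np.random.default_rng(6)
        n = 90
        outcome = (rng.random(n) < 0.3).astype(int)
        t = FeatureTable(np.zeros((n, 1)), ("c",), outcome)
        mean, _ = cv_score(t, (0,), fast_wrapper_config())
        majority = max(outcome.mean(), 1 - outcome.mean())
        assert mean == pytest.approx(majority, abs=0.1)

    def test_fold_scores_satisfy_step_stat_identities(self, tiny_table):
        cfg = fast_wrapper_config(cv_folds=5)
        _, folds = cv_score(tiny_table, (0,), cfg)
        s = make_step_stats(folds, (0,), ("sig",))
        assert s.std_err == pytest.approx(s.std_dev / np.sqrt(len(folds) - 1))
        assert s.ci_bound == pytest.approx(
            s.std_err * stats.t.ppf(0.975, df=len(folds))
        )


class TestStepStats:
    def test_reference_std_err_and_ci(self):
        # four fold scores with population SD 0.0702348 around 0.735426
        mu, sd = 0.735426, 0.0702348
        folds = [mu - sd, mu + sd, mu - sd, mu + sd]
        s = make_step_stats(folds, (1,), ("FSH",))
        assert s.avg_score == pytest.approx(mu)
        assert s.std_dev == pytest.approx(sd, abs=1e-9)
        assert s.std_err == pytest.approx(0.0405501, abs=1e-5)
        assert s.ci_bound == pytest.approx(0.112585, abs=1e-5)

    def test_identical_scores_have_zero_spread(self):
        s = make_step_stats([0.75, 0.75, 0.75], (0,), ("a",))
        assert s.std_dev == s.std_err == s.ci_bound == 0.0

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            make_step_stats([0.7], (0,), ("a",))


class TestSequentialSearches:
    def test_sfs_first_pick_is_the_separating_feature(self, tiny_table):
        cfg = fast_wrapper_config(target_k=1)
        trace = sfs(tiny_table, range(4), cfg)
        assert trace.final_subset == (0,)
        assert len(trace.steps) == 1

    def test_sfs_full_pool_boundary(self, tiny_table):
        cfg = fast_wrapper_config(target_k=4)
        trace = sfs(tiny_table, range(4), cfg)
        assert trace.final_subset == (0, 1, 2, 3)
        assert len(trace.steps) == 4

    def test_sbs_identity_boundary(self, tiny_table):
        cfg = fast_wrapper_config(target_k=4)
        trace = sbs(tiny_table, range(4), cfg)
        assert trace.final_subset == (0, 1, 2, 3)
        assert len(trace.steps) == 1

    def test_sbs_first_elimination_matches_exhaustive_subset(self):
        # the first greedy elimination equals the best (p-1)-subset;
        # later steps are path-dependent and need not match enumeration
        table = random_small_table(3, p=4)
        cfg = fast_wrapper_config(target_k=2)
        trace = sbs(table, range(4), cfg)
        best_score, _ = exhaustive_best(table, range(4), 3, cfg)
        # score equality: the greedy elimination is exhaustive over
        # (p-1)-subsets (subsets may differ only via tie-break order)
        assert trace.steps[1].avg_score == pytest.approx(best_score, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_sfs_step1_matches_exhaustive_singleton(self, seed):
        table = random_small_table(seed)
        cfg = fast_wrapper_config(target_k=1)
        trace = sfs(table, range(table.p), cfg)
        _, expected = exhaustive_best(table, range(table.p), 1, cfg)
        assert trace.final_subset == expected

    def test_trace_subsets_are_nested_and_within_pool(self):
        table = random_small_table(1)
        cfg = fast_wrapper_config(target_k=3)
        trace = sfs(table, range(table.p), cfg)
        sizes = [len(s.feature_idx) for s in trace.steps]
        assert sizes == [1, 2, 3]
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert set(a.feature_idx) <= set(b.feature_idx)

    def test_reproducible_traces(self):
        table = random_small_table(2)
        cfg = fast_wrapper_config(target_k=2)
        t1 = sfs(table, range(table.p), cfg)
        t2 = sfs(table, range(table.p), cfg)
        # runtime is wall clock; everything else must be identical
        assert t1.steps == t2.steps
        assert t1.final_subset == t2.final_subset


class TestFloatingSearches:
    @pytest.mark.parametrize("seed", range(5))
    def test_sffs_never_below_sfs_and_never_above_optimum(self, seed):
        table = random_small_table(seed)
        cfg = fast_wrapper_config(target_k=3)
        pool = range(table.p)
        greedy = sfs(table, pool, cfg)
        floating = sffs(table, pool, cfg)
        optimum, _ = exhaustive_best(table, pool, 3, cfg)
        greedy_score, _ = cv_score(table, greedy.final_subset, cfg)
        floating_score, _ = cv_score(table, floating.final_subset, cfg)
        assert floating_score >= greedy_score - 1e-12
        assert floating_score <= optimum + 1e-12

    def test_sffs_recovers_jointly_informative_pair(self):
        # XOR-style pair: informative only jointly; a decoy is the best
        # singleton, so plain greedy forward search can miss the pair
        rng = np.random.default_rng(0)
        n = 120
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        outcome = a ^ b
        decoy = outcome + rng.normal(0, 2.0, n)  # weak singleton signal
        values = np.column_stack(
            [a + rng.normal(0, 0.05, n), b + rng.normal(0, 0.05, n),
             decoy, rng.normal(size=n)]
        )
        table = FeatureTable(values, ("a", "b", "decoy", "noise"), outcome)
        cfg = fast_wrapper_config(target_k=2, cv_folds=4)
        _, optimum_pair = exhaustive_best(table, range(4), 2, cfg)
        assert optimum_pair == (0, 1)  # construction sanity check
        floating = sffs(table, range(4), cfg)
        assert floating.final_subset == (0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_sfbs_never_below_sbs_and_never_above_optimum(self, seed):
        table = random_small_table(seed, p=5)
        cfg = fast_wrapper_config(target_k=3)
        pool = range(table.p)
        greedy = sbs(table, pool, cfg)
        floating = sfbs(table, pool, cfg)
        optimum, _ = exhaustive_best(table, pool, 3, cfg)
        greedy_score, _ = cv_score(table, greedy.final_subset, cfg)
        floating_score, _ = cv_score(table, floating.final_subset, cfg)
        assert floating_score >= greedy_score - 1e-12
        assert floating_score <= optimum + 1e-12


class TestRandomSearch:
    def test_single_iteration_returns_the_sampled_subset(self):
        table = random_small_table(4)
        cfg = fast_wrapper_config(random_search_iters=1)
        trace = random_search(table, range(table.p), cfg)
        assert len(trace.steps) == 1
        assert trace.final_subset == trace.steps[0].feature_idx

    def test_many_iterations_match_exhaustive_optimum(self):
        table = random_small_table(5, p=5)
        cfg = fast_wrapper_config(random_search_iters=300)
        trace = random_search(table, range(5), cfg)
        best_score = None
        for size in range(1, 6):
            mean, _ = exhaustive_best(table, range(5), size, cfg)
            best_score = mean if best_score is None else max(best_score, mean)
        found, _ = cv_score(table, trace.final_subset, cfg)
        assert found == pytest.approx(best_score, abs=1e-12)

    def test_seed_reproducibility(self):
        table = random_small_table(6)
        cfg = fast_wrapper_config(random_search_iters=20)
        t1 = random_search(table, range(table.p), cfg)
        t2 = random_search(table, range(table.p), cfg)
        assert t1.final_subset == t2.final_subset
        assert t1.steps == t2.steps
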