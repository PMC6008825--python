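"""Scatter-search beam-angle optimization: metric, operators, search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imrtbao.bao import (
    ScatterSearchParams,
    ScoreCache,
    canonical,
    combine_solutions,
    config_distance,
    exhaustive_search,
    generate_diverse_population,
    local_improve,
    scatter_search_bao,
    score_configuration,
)
from imrtbao.dose_engine import enumerate_candidates
from imrtbao.fmo import get_prescription

POOL10 = enumerate_candidates(10)
POOL30 = enumerate_candidates(30)
POOL90 = enumerate_candidates(90)


@pytest.fixture(scope="module")
def small_box_setup(small_box_phantom):
    """Shared scoring cache on the coarse box phantom."""
    rx = get_prescription("box")
    cache = ScoreCache(small_box_phantom, rx)
    return small_box_phantom, rx, cache


class TestConfigDistance:
    def test_identity_is_zero(self):
        assert config_distance((0, 90), (0, 90)) == 0.0

    def test_circular_wraparound(self):
        assert config_distance((0,), (350,)) == pytest.approx(10.0)

    def test_matched_pairs_root_sum_square(self):
        assert config_distance((0, 180), (10, 170)) == pytest.approx(
            np.sqrt(200.0)
        )

    def test_mismatched_beam_counts_raise(self):
        with pytest.raises(ValueError):
            config_distance((0, 90), (0, 90, 180))

    @given(
        a=st.lists(st.sampled_from([i * 10.0 for i in range(36)]),
                   min_size=3, max_size=3, unique=True),
        b=st.lists(st.sampled_from([i * 10.0 for i in range(36)]),
                   min_size=3, max_size=3, unique=True),
    )
    @settings(max_examples=60, deadline=None)
    def test_metric_properties(self, a, b):
        d_ab = config_distance(a, b)
        assert d_ab == pytest.approx(config_distance(b, a))
        assert d_ab >= 0.0
        assert (d_ab == pytest.approx(0.0, abs=1e-12)) == (set(a) == set(b))


class TestCombineSolutions:
    def test_identical_parents_are_idempotent(self):
        trials = combine_solutions((0, 180), (0, 180), POOL10)
        assert trials == [(0.0, 180.0)]

    def test_midpoint_interpolation_snaps_to_pool(self):
        trials = combine_solutions((0, 180), (20, 200), POOL10)
        assert (10.0, 190.0) in trials

    def test_wraparound_midpoint(self):
        trials = combine_solutions((350, 170), (10, 190), POOL10)
        assert (0.0, 180.0) in trials

    def test_trials_are_valid_distinct_configurations(self):
        for a, b in [((0, 10, 20), (180, 190, 200)), ((0, 120, 240), (10, 130, 250))]:
            for t in combine_solutions(a, b, POOL10):
                assert len(set(t)) == len(t)
                assert all(x in POOL10.angles for x in t)


class TestDiversePopulation:
    def test_single_member_is_equispaced_from_seeded_start(self):
        pop = generate_diverse_population(POOL10, 4, 1, seed=123)
        gaps = sorted((pop[0][(i + 1) % 4] - pop[0][i]) % 360 for i in range(4))
        assert gaps == [90.0, 90.0, 90.0, 90.0]

    def test_members_pairwise_distinct(self):
        pop = generate_diverse_population(POOL10, 3, 12, seed=5)
        assert len({tuple(c) for c in pop}) == 12

    def test_deterministic_for_a_seed(self):
        a = generate_diverse_population(POOL10, 3, 8, seed=9)
        b = generate_diverse_population(POOL10, 3, 8, seed=9)
        assert a == b

    def test_infeasible_size_raises(self):
        with pytest.raises(ValueError):
            generate_diverse_population(POOL90, 4, 2, seed=0)


class TestScoring:
    def test_memoized_scores_are_stable_and_free(self, small_box_setup):
        ph, rx, cache = small_box_setup
        cfg = (0.0, 90.0, 180.0, 270.0)
        f1 = score_configuration(cfg, ph, rx, cache)
        n_evals = cache.evaluations
        f2 = score_configuration(tuple(reversed(cfg)), ph, rx, cache)
        assert f1 == f2
        assert cache.evaluations == n_evals  # cache hit

    def test_lower_objective_for_spread_beams(self, small_box_setup):
        """Spread beams beat tightly clustered ones on the box phantom."""
        ph, rx, cache = small_box_setup
        f_spread = cache.score((0.0, 90.0, 180.0, 270.0))
        f_cluster = cache.score((0.0, 10.0, 20.0, 30.0))
        assert f_spread < f_cluster

    def test_axis_aligned_beats_rotated_equispaced(self, small_box_setup):
        """Perpendicular face entry has the shortest radiological path."""
        ph, rx, cache = small_box_setup
        assert cache.score((0.0, 90.0, 180.0, 270.0)) <= cache.score(
            (10.0, 100.0, 190.0, 280.0)
        )


class TestLocalImprove:
    def test_descent_contract(self, small_box_setup):
        ph, rx, cache = small_box_setup
        start = (0.0, 30.0, 60.0, 90.0)
        f_start = cache.score(start)
        cfg, f = local_improve(start, cache.score, POOL10)
        assert f <= f_start

    def test_local_minimum_is_fixed_point(self, small_box_setup):
        ph, rx, cache = small_box_setup
        cfg, f = local_improve((0.0, 90.0, 180.0, 270.0), cache.score, POOL30)
        cfg2, f2 = local_improve(cfg, cache.score, POOL30)
        assert cfg2 == cfg and f2 == f

    def test_reaches_exhaustive_minimum_on_coarse_pool(self, small_box_setup):
        """Descent from a lopsided start matches enumeration on the 90° pool."""
        ph, rx, cache = small_box_setup
        ex = exhaustive_search(ph, rx, POOL90, 2, cache=cache)
        cfg, f = local_improve((0.0, 90.0), cache.score, POOL90)
        assert f == pytest.approx(ex.best_objective, rel=1e-9)

    def test_budget_limits_score_calls(self, small_box_setup):
        ph, rx, cache = small_box_setup
        calls = []

        def counting_score(c):
            calls.append(c)
            return cache.score(c)

        local_improve((0.0, 30.0, 60.0, 90.0), counting_score, POOL10, budget=5)
        assert len(calls) <= 6  # start evaluation plus the budgeted moves


class TestScatterSearch:
    def test_matches_exhaustive_minimum_with_full_budget(self, small_box_setup):
        ph, rx, cache = small_box_setup
        ex = exhaustive_search(ph, rx, POOL90, 2,
                               cache=ScoreCache(ph, rx,
                                                matrix_cache=cache.matrices))
        params = ScatterSearchParams(population_size=4, refset_size=4,
                                     eval_budget=6, seed=0)
        res = scatter_search_bao(ph, rx, POOL90, 2, params,
                                 cache=ScoreCache(ph, rx,
                                                  matrix_cache=cache.matrices))
        # ties between symmetry-equivalent configurations are accepted
        assert res.best_objective == pytest.approx(ex.best_objective, rel=1e-9)

    def test_seeded_runs_are_identical(self, small_box_setup):
        ph, rx, cache = small_box_setup
        params = ScatterSearchParams(population_size=6, refset_size=4,
                                     eval_budget=25, seed=42)
        results = [
            scatter_search_bao(ph, rx, POOL30, 2, params,
                               cache=ScoreCache(ph, rx,
                                                matrix_cache=cache.matrices))
            for _ in range(2)
        ]
        assert results[0].solutions == results[1].solutions
        assert results[0].evaluations == results[1].evaluations
        assert results[0].trace == results[1].trace

    def test_incumbent_is_minimum_over_all_scored(self, small_box_setup):
        ph, rx, _ = small_box_setup
        cache = ScoreCache(ph, rx)
        params = ScatterSearchParams(population_size=6, refset_size=4,
                                     eval_budget=30, seed=3)
        res = scatter_search_bao(ph, rx, POOL30, 3, params, cache=cache)
        assert res.best_objective == min(cache.scores.values())
        fs = [f for _, f in res.solutions]
        assert fs == sorted(fs)

    def test_budget_below_population_scoring_raises(self, small_box_setup):
        ph, rx, cache = small_box_setup
        params = ScatterSearchParams(population_size=10, refset_size=4,
                                     eval_budget=8, seed=0)
        with pytest.raises(ValueError):
            scatter_search_bao(ph, rx, POOL30, 2, params)

    def test_best_so_far_trace_is_decreasing(self, small_box_setup):
        ph, rx, cache = small_box_setup
        params = ScatterSearchParams(population_size=6, refset_size=4,
                                     eval_budget=30, seed=1)
        res = scatter_search_bao(ph, rx, POOL30, 3, params,
                                 cache=ScoreCache(ph, rx,
                                                  matrix_cache=cache.matrices))
        best_values = [f for _, f in res.trace]
        assert best_values == sorted(best_values, reverse=True)


def test_canonical_sorts_and_wraps():
    assert canonical([270, 0.0, 450.0]) == (0.0, 90.0, 270.0)
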