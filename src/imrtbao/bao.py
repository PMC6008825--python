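"""Beam-angle optimization by scatter search over coplanar gantry angles.

The outer loop searches the discrete space of n-beam configurations drawn
from an equally spaced candidate pool; each configuration theta is scored
by the optimal fluence-map objective F(theta) = min_x F(x | theta) from
:mod:`imrtbao.fmo` (lower is better). Scatter search maintains a reference
set of elite and diverse configurations, combines reference pairs into
trial points by circular interpolation, improves promising trials with a
discrete first-improvement coordinate descent (the local solver on the
angle grid), and bookkeeps spherical basins of attraction around local
optima so redundant local solves are skipped. The budget is counted in FMO
evaluations (cache misses), which makes seeded runs exactly reproducible;
wall-clock MaxTime is an optional secondary cap.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .dose_engine import CandidatePool, DoseMatrixCache, KernelParams, circular_difference
from .fmo import FmoSolverParams, Prescription, solve_fmo
from .phantoms import Phantom

BeamConfiguration = tuple[float, ...]


def canonical(angles) -> BeamConfiguration:
    """Canonical form of a configuration: ascending sorted tuple of floats."""
    return tuple(sorted(float(a) % 360.0 for a in angles))


def validate_configuration(config, pool: CandidatePool, n_beams: int | None = None) -> BeamConfiguration:
    cfg = canonical(config)
    if n_beams is not None and len(cfg) != n_beams:
        raise ValueError(f"expected {n_beams} beams, got {len(cfg)}")
    if len(set(cfg)) != len(cfg):
        raise ValueError(f"configuration has duplicate angles: {cfg}")
    pool_set = set(float(a) for a in pool.angles)
    if not set(cfg) <= pool_set:
        raise ValueError(f"configuration {cfg} contains angles outside the pool")
    return cfg


# --------------------------------------------------------------------------
# scoring with memoization


class BudgetExhausted(Exception):
    """Raised when the FMO evaluation budget is spent."""


class ScoreCache:
    """Memoized configuration scores on top of a shared dose-matrix cache.

    ``evaluations`` counts FMO solves (cache misses) only; re-scoring a
    configuration is free, mirroring how the outer search treats repeated
    trial points.
    """

    def __init__(
        self,
        phantom: Phantom,
        prescription: Prescription,
        kernel_params: KernelParams | None = None,
        solver_params: FmoSolverParams | None = None,
        beamlet_size_cm: float = 1.0,
        matrix_cache: DoseMatrixCache | None = None,
    ):
        self.phantom = phantom
        self.prescription = prescription
        self.solver_params = solver_params or FmoSolverParams()
        self.matrices = matrix_cache or DoseMatrixCache(
            phantom, kernel_params, beamlet_size_cm
        )
        self.scores: dict[BeamConfiguration, float] = {}
        self.evaluations = 0
        self.budget: int | None = None

    def __contains__(self, config) -> bool:
        return canonical(config) in self.scores

    def score(self, config) -> float:
        cfg = canonical(config)
        if cfg in self.scores:
            return self.scores[cfg]
        if self.budget is not None and self.evaluations >= self.budget:
            raise BudgetExhausted
        mats = self.matrices.get_config(cfg)
        result = solve_fmo(mats, self.prescription, self.phantom, self.solver_params)
        self.evaluations += 1
        self.scores[cfg] = result.objective
        return result.objective


def score_configuration(config, phantom: Phantom, prescription: Prescription,
                        cache: ScoreCache) -> float:
    """Optimal FMO value of a beam configuration, memoized in ``cache``."""
    if cache.phantom is not phantom or cache.prescription != prescription:
        raise ValueError("cache was built for a different phantom or prescription")
    return cache.score(config)


# --------------------------------------------------------------------------
# configuration geometry


def config_distance(config_a, config_b, pool: CandidatePool | None = None) -> float:
    """Optimal-matching root-sum-square circular distance between configurations."""
    a = canonical(config_a)
    b = canonical(config_b)
    if len(a) != len(b):
        raise ValueError(f"configurations have different beam counts: {len(a)} vs {len(b)}")
    cost = np.array([[circular_difference(x, y) ** 2 for y in b] for x in a])
    ri, ci = linear_sum_assignment(cost)
    return float(np.sqrt(cost[ri, ci].sum()))


def _matched_pairs(a: BeamConfiguration, b: BeamConfiguration):
    cost = np.array([[circular_difference(x, y) ** 2 for y in b] for x in a])
    ri, ci = linear_sum_assignment(cost)
    return [(a[i], b[j]) for i, j in zip(ri, ci)]


def _snap(angle: float, pool: CandidatePool) -> float:
    from .dose_engine import snap_to_pool

    return snap_to_pool(angle, pool)


def _repair_duplicates(angles: list[float], pool: CandidatePool) -> BeamConfiguration:
    """Move duplicate angles to the nearest unused pool angle (ties clockwise)."""
    used: list[float] = []
    pool_angles = list(pool.angles)
    for a in angles:
        if a not in used:
            used.append(a)
            continue
        free = [p for p in pool_angles if p not in used]
        if not free:
            raise ValueError("pool too small to repair duplicate angles")
        dists = [circular_difference(a, p) for p in free]
        best = min(dists)
        tied = [p for p, d in zip(free, dists) if abs(d - best) < 1e-9]
        if len(tied) == 1:
            used.append(tied[0])
        else:
            fwd = [(p - a) % 360.0 for p in tied]
            used.append(tied[int(np.argmin([abs(f - best) for f in fwd]))])
    return canonical(used)


def combine_solutions(parent_a, parent_b, pool: CandidatePool,
                      lambdas=(0.25, 0.5, 0.75)) -> list[BeamConfiguration]:
    """Circularly interpolate matched parent angles and snap to the pool.

    For each mixing weight, every matched pair of parent angles is
    interpolated along the shorter arc, snapped to the nearest pool angle,
    and duplicate angles are repaired; the deduplicated valid trials are
    returned (at most one per mixing weight).
    """
    a = canonical(parent_a)
    b = canonical(parent_b)
    if len(a) != len(b):
        raise ValueError("parents must have the same number of beams")
    pairs = _matched_pairs(a, b)
    trials: list[BeamConfiguration] = []
    for lam in lambdas:
        angles = []
        for alpha, beta in pairs:
            delta = ((beta - alpha + 180.0) % 360.0) - 180.0  # signed shorter arc
            angles.append(_snap((alpha + lam * delta) % 360.0, pool))
        cfg = _repair_duplicates(angles, pool)
        if cfg not in trials:
            trials.append(cfg)
    return trials


# --------------------------------------------------------------------------
# population, local search


def generate_diverse_population(pool: CandidatePool, n_beams: int,
                                population_size: int, seed) -> list[BeamConfiguration]:
    """Greedy max-min diverse set of configurations, deterministic per seed.

    The first member is the equispaced configuration anchored at a random
    pool angle; each following member is the best of a batch of random
    candidates, maximizing its minimum distance to the already selected.
    """
    import math

    if math.comb(pool.n_angles, n_beams) < population_size:
        raise ValueError("population_size exceeds the number of distinct configurations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = float(rng.choice(pool.angles))
    first = _repair_duplicates(
        [_snap(start + k * 360.0 / n_beams, pool) for k in range(n_beams)], pool
    )
    population = [first]
    batch = 30
    guard = 0
    while len(population) < population_size and guard < 10000:
        guard += 1
        candidates = []
        for _ in range(batch):
            angles = rng.choice(pool.n_angles, size=n_beams, replace=False)
            cfg = canonical(pool.angles[i] for i in angles)
            if cfg not in population:
                candidates.append(cfg)
        if not candidates:
            continue
        dmin = [min(config_distance(c, p) for p in population) for c in candidates]
        population.append(candidates[int(np.argmax(dmin))])
    if len(population) < population_size:
        raise RuntimeError("failed to build a diverse population of the requested size")
    return population


def _neighbors(config: BeamConfiguration, angle: float, pool: CandidatePool):
    """Single-step moves of one angle on the pool circle, clockwise first."""
    angles = list(pool.angles)
    i = angles.index(angle)
    n = len(angles)
    for j in (i + 1, i - 1):  # clockwise (+1 step) tried first
        cand = angles[j % n]
        if cand not in config:
            yield canonical([a for a in config if a != angle] + [cand])


def local_improve(config, score_fn, pool: CandidatePool,
                  budget: int | None = None) -> tuple[BeamConfiguration, float]:
    """First-improvement coordinate descent on the discrete angle grid.

    Cycles through the configuration's angles in ascending order, tries
    moving each by one pool step in either direction, accepts any strict
    improvement and restarts the cycle; stops at a local minimum or when
    ``budget`` score evaluations have been used. Never returns a worse
    configuration than the start.
    """
    current = canonical(config)
    f_cur = score_fn(current)
    calls = 0
    improved = True
    while improved:
        improved = False
        for angle in list(current):
            for cand in _neighbors(current, angle, pool):
                if budget is not None and calls >= budget:
                    return current, f_cur
                f_new = score_fn(cand)
                calls += 1
                if f_new < f_cur:
                    current, f_cur = cand, f_new
                    improved = True
                    break
            if improved:
                break
    return current, f_cur


# --------------------------------------------------------------------------
# scatter search


@dataclass(frozen=True)
class ScatterSearchParams:
    population_size: int = 30
    refset_size: int = 10  # half elite by score, half most diverse
    eval_budget: int = 200  # FMO evaluations (cache misses)
    max_time_s: float | None = None
    basin_overlap_limit: int = 20
    basin_shrink_factor: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.refset_size > self.population_size:
            raise ValueError("refset_size must not exceed population_size")
        if self.eval_budget < self.refset_size:
            raise ValueError("eval_budget must be at least refset_size")
        if not 0 < self.basin_shrink_factor < 1:
            raise ValueError("basin_shrink_factor must lie in (0, 1)")


@dataclass
class Basin:
    center: BeamConfiguration
    radius: float
    counter: int = 0

    def contains(self, config: BeamConfiguration) -> bool:
        return config_distance(self.center, config) <= self.radius


@dataclass
class BAOResult:
    """Distinct locally optimal configurations, best first."""

    solutions: list[tuple[BeamConfiguration, float]]
    evaluations: int
    seed: int
    trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def best_configuration(self) -> BeamConfiguration:
        return self.solutions[0][0]

    @property
    def best_objective(self) -> float:
        return self.solutions[0][1]


def exhaustive_search(phantom: Phantom, prescription: Prescription,
                      pool: CandidatePool, n_beams: int,
                      cache: ScoreCache | None = None) -> BAOResult:
    """Brute-force enumeration of every n-beam configuration (small pools)."""
    cache = cache or ScoreCache(phantom, prescription)
    evals_start = cache.evaluations
    scored = []
    for combo in itertools.combinations(pool.angles, n_beams):
        cfg = canonical(combo)
        scored.append((cfg, cache.score(cfg)))
    scored.sort(key=lambda cf: (cf[1], cf[0]))
    return BAOResult(solutions=scored, evaluations=cache.evaluations - evals_start,
                     seed=-1)


def _select_refset(scored: dict[BeamConfiguration, float], size: int):
    """Half best by objective, half greedily maximizing min pairwise distance."""
    ranked = sorted(scored.items(), key=lambda cf: (cf[1], cf[0]))
    n_elite = size // 2
    refset = [cfg for cfg, _ in ranked[:n_elite]]
    rest = [cfg for cfg, _ in ranked[n_elite:]]
    while len(refset) < size and rest:
        dmin = [min(config_distance(c, r) for r in refset) for c in rest]
        pick = int(np.argmax(dmin))
        refset.append(rest.pop(pick))
    return refset


def _refset_min_dist(refset) -> float:
    if len(refset) < 2:
        return np.inf
    return min(config_distance(a, b) for a, b in itertools.combinations(refset, 2))


def _update_refset(refset, candidate, scored) -> bool:
    """Quality-or-diversity replacement; duplicates never enter."""
    if candidate in refset:
        return False
    worst = max(refset, key=lambda c: (scored[c], c))
    if scored[candidate] < scored[worst]:
        refset[refset.index(worst)] = candidate
        return True
    base = _refset_min_dist(refset)
    best_gain, best_idx = 0.0, None
    for i in range(len(refset)):
        trial = refset[:i] + [candidate] + refset[i + 1:]
        gain = _refset_min_dist(trial) - base
        if gain > best_gain:
            best_gain, best_idx = gain, i
    if best_idx is not None:
        refset[best_idx] = candidate
        return True
    return False


def scatter_search_bao(phantom: Phantom, prescription: Prescription,
                       pool: CandidatePool, n_beams: int,
                       params: ScatterSearchParams | None = None,
                       cache: ScoreCache | None = None) -> BAOResult:
    """Scatter search with basin bookkeeping over n-beam configurations.

    Builds a diverse scored population, keeps a reference set of elite and
    diverse members, combines all reference pairs into trial points, runs
    the discrete local solver from trials that are neither inside a known
    basin of attraction nor worse than the local-solver threshold, and
    repeats (rediversifying when progress stalls) until the FMO evaluation
    budget or MaxTime is exhausted. With a budget at least the size of the
    configuration space the run degenerates into exhaustive enumeration, so
    the incumbent provably equals the global minimum.
    """
    import math

    params = params or ScatterSearchParams()
    cache = cache or ScoreCache(phantom, prescription)
    if params.eval_budget < params.population_size:
        raise ValueError("eval_budget is smaller than one population scoring")
    evals_start = cache.evaluations
    cache.budget = cache.evaluations + params.eval_budget
    t0 = time.monotonic()
    rng = np.random.default_rng(params.seed)

    scored: dict[BeamConfiguration, float] = {}
    trace: list[tuple[int, float]] = []
    solutions: dict[BeamConfiguration, float] = {}
    basins: list[Basin] = []
    threshold = np.inf
    threshold_counter = 0
    best_f = np.inf

    def out_of_time() -> bool:
        return params.max_time_s is not None and time.monotonic() - t0 > params.max_time_s

    def score(cfg: BeamConfiguration) -> float:
        nonlocal best_f
        f = cache.score(cfg)
        if cfg not in scored:
            scored[cfg] = f
            if f < best_f:
                best_f = f
                trace.append((cache.evaluations, f))
        return f

    def run_local(start: BeamConfiguration, f_start: float) -> BeamConfiguration:
        nonlocal threshold, threshold_counter
        opt, f_opt = local_improve(start, score, pool)
        solutions[opt] = f_opt
        radius = config_distance(start, opt)
        basins.append(Basin(center=opt, radius=radius))
        threshold = min(threshold, f_start)
        threshold_counter = 0
        for b in basins:
            b.counter = 0
        return opt

    try:
        population = generate_diverse_population(
            pool, n_beams, params.population_size, rng
        )
        for cfg in population:
            score(cfg)
        refset = _select_refset(scored, min(params.refset_size, len(scored)))
        # stage 1: local solve from the best population member
        start = min(scored, key=lambda c: (scored[c], c))
        run_local(start, scored[start])

        stalled_rounds = 0
        while not out_of_time():
            evals_before = cache.evaluations
            trials: list[BeamConfiguration] = []
            for a, b in itertools.combinations(sorted(refset), 2):
                for t in combine_solutions(a, b, pool):
                    if t not in trials:
                        trials.append(t)
            for trial in trials:
                if out_of_time():
                    break
                f_t = score(trial)
                hit = next((bs for bs in basins if bs.contains(trial)), None)
                if hit is not None:
                    hit.counter += 1
                    if hit.counter > params.basin_overlap_limit:
                        hit.radius *= params.basin_shrink_factor
                        hit.counter = 0
                    continue
                if f_t > threshold:
                    threshold_counter += 1
                    if threshold_counter > params.basin_overlap_limit:
                        threshold /= params.basin_shrink_factor
                        threshold_counter = 0
                    continue
                opt = run_local(trial, f_t)
                _update_refset(refset, opt, scored)
            if cache.evaluations == evals_before:
                stalled_rounds += 1
            else:
                stalled_rounds = 0
            if stalled_rounds == 1:
                # rediversify: new population, rebuilt reference set
                population = generate_diverse_population(
                    pool, n_beams, params.population_size, rng
                )
                for cfg in population:
                    score(cfg)
                refset = _select_refset(scored, min(params.refset_size, len(scored)))
            elif stalled_rounds >= 2:
                # systematic sweep of unevaluated configurations (exhaustive tail)
                if math.comb(pool.n_angles, n_beams) <= max(
                    10 * params.eval_budget, 100000
                ):
                    for combo in itertools.combinations(pool.angles, n_beams):
                        if out_of_time():
                            break
                        cfg = canonical(combo)
                        if cfg not in cache:
                            score(cfg)
                break
    except BudgetExhausted:
        pass

    # the incumbent (best configuration ever scored) always enters the result
    incumbent = min(scored, key=lambda c: (scored[c], c))
    solutions.setdefault(incumbent, scored[incumbent])
    ordered = sorted(solutions.items(), key=lambda cf: (cf[1], cf[0]))
    cache.budget = None
    return BAOResult(
        solutions=ordered,
        evaluations=cache.evaluations - evals_start,
        seed=params.seed,
        trace=trace,
    )
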