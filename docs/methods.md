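# Methods

## Problem and model

`imrtbao` selects coplanar gantry angles for intensity-modulated radiation
therapy (IMRT). The search space is the set of unordered n-beam
configurations θ = (b₁,…,bₙ) drawn from an equally spaced candidate pool
covering [0°, 360°); each configuration is scored by the optimal value of
the fluence-map-optimization (FMO) problem it admits,

    F(θ) = min_{x ≥ 0}  Σ_T Σ_{i∈T} p_T (D_i − D^pres_T)²
                      + Σ_O Σ_{i∈O} p_O ⌊D_i − D^max_O⌋₊² ,
    D = K(θ) x ,   ⌊u⌋₊ = max(u, 0),

summing over target structures T and organ-at-risk/body structures O.
Target voxels are penalized quadratically for any deviation from the
prescribed dose; OAR and body voxels only when they exceed their
maximum-dose threshold, so satisfied constraints contribute nothing. Lower
F means a better plan. The outer problem min F(θ) over configurations is
combinatorial (C(36, 4) = 58905 already for four beams on a 10° pool) and
is attacked with scatter search; the inner problem is convex in x and is
solved to its optimum for every configuration visited.

## Synthetic phantoms

Three voxel phantoms make every stage runnable with no external data:

* **box** — square-section body (20 cm × 20 cm × 10 cm, 0.5 cm voxels,
  32 000 body voxels) with a centred cubic PTV of 2 cm half-width. The
  phantom is exactly invariant under 90° rotations about the isocenter,
  which supplies a strong engine-level oracle.
* **tg119** — cylindrical body with a C-shaped (annular, angular gap) PTV
  wrapped around a central cylindrical core OAR, the classic concave
  commissioning geometry.
* **prostate** — two nested ellipsoidal targets (a 68 Gy boost inside a
  56 Gy volume, stored as disjoint voxel sets), an anterior bladder
  ellipsoid, a posterior rectum cylinder and a rectangular body.

A voxel belongs to a structure iff its centre lies inside the analytic
shape; no partial volumes. Where shapes touch, targets claim the voxel
over OARs, mirroring PTV-priority booleans in planning systems. Geometry
parameters (radii, offsets) are package choices at desk scale, not
replicas of any clinical dataset; z-extents are kept thin by default so
matrices stay small while dose and optimization remain fully 3-D.

## Dose engine

Dose-influence matrices use a parallel (non-divergent) pencil-beam kernel
evaluated at body voxel centres:

    K_im = exp(−μ·depth_i) · exp(−d⊥²/(2σ²)) / (√(2π)·σ)

with `depth_i` the water-equivalent path length (unit density) from the
body entry point to the voxel, ray-marched at half-voxel steps, and `d⊥`
the 3-D distance from the voxel centre to the beamlet axis. Defaults:
μ = 0.04 cm⁻¹ (effective 6-MV attenuation), σ = 0.5 cm (lateral spread),
relative sparsity cutoff 10⁻⁴ per column. Beamlets tile the bounding box
of the target projection on the isocenter plane with a one-beamlet margin
(1 × 1 cm² beamlets by default). Gantry 0° enters from the anterior (+y);
angles increase clockwise viewed from the patient's feet.

Parallel geometry preserves the box phantom's exact four-fold symmetry
(rotating the phantom by 90° maps the matrix for gantry a onto a + 90°,
asserted in tests), but it has one important consequence, documented
under *Limitations*: a beam and its opposite traverse the same voxel
column, so opposed beams are nearly redundant.

## FMO solver

Polak–Ribière nonlinear conjugate gradient on the piecewise-quadratic
objective with projection onto x ≥ 0: steps come from the local quadratic
model α = −gᵀd / dᵀHd (H restricted to the active hinge rows), halved
until monotone descent holds; the direction resets to projected steepest
descent whenever the bound active set changes. Initialization x = 0
(deterministic and feasible). Stopping: relative objective change below
`rel_tol` (default 10⁻⁶) on three consecutive iterations, or `max_iters`
(default 200). The objective is convex and C¹, so all starts reach the
same optimum; unit tests verify agreement with an independent
bound-constrained quasi-Newton solve to 10⁻⁶ relative on random small
instances. The body overdosing term excludes target voxels by default
(`body_excludes_targets=True`), otherwise it would fight the target
prescription wherever thresholds sit below prescribed doses. Objective
values are raw voxel sums (no volume normalization), one penalty per
structure. For the prostate preset the 45 Gy bladder/rectum level is used
as the square-overdosing threshold.

## Scatter search

The outer loop maintains a reference set of 10 configurations (5 elite by
F, 5 chosen greedily to maximize the minimum pairwise distance) drawn
from a diverse population of 30. The distance between configurations is
the optimal-assignment root-sum-square of circular angle differences.
Every reference pair is combined by circular interpolation of matched
angles at λ ∈ {0.25, 0.5, 0.75}, snapped to the pool (ties clockwise)
with duplicate repair. A trial point is locally improved — discrete
first-improvement coordinate descent, one pool step per move — unless it
lies inside a known basin of attraction (a sphere around a previous local
optimum with radius equal to its start-to-optimum distance) or scores
worse than the local-solver threshold (the best start score seen so far);
consecutive skips beyond `basin_overlap_limit` shrink the basin radius by
0.75 or relax the threshold. When a round adds no new evaluations the
search rediversifies, and if that also stalls it sweeps unevaluated
configurations in canonical order, so a budget of at least C(N, n)
degenerates into exhaustive enumeration and the incumbent provably equals
the global minimum (asserted against brute force on C(12, 3) = 220).

The budget is counted in FMO evaluations (cache misses): identical seeds
and parameters reproduce identical results bit for bit, which a property
test asserts. Wall-clock `max_time_s` is an optional secondary cap, off
by default. All numeric scatter-search parameters (population 30, refset
10, overlap limit 20, shrink 0.75) are package defaults chosen at desk
scale; nothing in the method is sensitive to them in the small-pool
oracle tests.

## Plan evaluation

Cumulative DVHs on a 0.1 Gy grid; D5/D95 by the exact rank-order
definition (hottest-q% minimum) so worked examples are bit-stable; the
homogeneity index HI = (D5 − D95)/D_p × 100 (0 ideal); the Van't Riet
conformity index CI = (V_t,ref/V_t)·(V_t,ref/V_ref) at the 95%-of-
prescription reference isodose (1 ideal; CI = 0 by convention when no
voxel reaches the reference level). For two-target cases each target is
evaluated against its own prescription. Comparison reports give plan-A-
minus-plan-B differences per metric.

## Problem sizes used in tests

The angle-recovery study runs at full study scale: 32 000 body voxels,
36 candidate angles, four beams, a 150-evaluation budget, three seeds.
Search-mechanics and property tests use a coarse 1-cm-voxel box (4 000
voxels) and small pools (4–12 angles); FMO oracle tests use random
instances with ≤ 20 voxels and ≤ 8 beamlets.

## Limitations

* **Opposed-beam redundancy.** With parallel geometry a beam and its
  opposite share one voxel column, so a two-opposed-pairs configuration
  such as {0°, 90°, 180°, 270°} spans only two distinct beam lines.
  Splitting a pair onto two nearby lines (say 270° → 260° and 0° → 350°)
  strictly enlarges the set of achievable dose distributions — it halves
  the through-strip dose crossing the PTV faces and de-overlaps entrance
  corridors — at almost no cost. On the box phantom the four-beam optimum
  of this engine therefore has four distinct beam lines with circular
  gaps such as (80°, 90°, 90°, 100°), rather than the textbook equispaced
  four-field box that divergent-beam dose engines produce; the axis-
  aligned equispaced set remains the best *two-line* plan and a local
  minimum of the discrete search. Source divergence, which breaks the
  redundancy in real treatment machines, is deliberately out of scope for
  this engine.
* No heterogeneity, scatter kernels, buildup, MLC transmission or
  deliverability constraints; doses are in Gy per arbitrary fluence unit.
* Dose-volume (percentile) constraints and biological objectives are not
  modelled; only quadratic one-sided penalties.
* Phantom presets are parametrized approximations of the benchmark
  geometries, not replicas, so absolute dosimetry is not comparable to
  published clinical tables; formula-level indices (HI, CI, dose
  differences) are.
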