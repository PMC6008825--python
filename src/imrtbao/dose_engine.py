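"""Candidate gantry angles, beamlet grids and pencil-beam dose-influence matrices.

The dose model is a parallel (non-divergent) pencil-beam kernel: exponential
depth attenuation along the beam direction times a lateral Gaussian around
each beamlet's central axis,

    K_im = exp(-mu * depth_i) * exp(-dperp^2 / (2 sigma^2)) / (sqrt(2 pi) sigma),

with ``depth_i`` the water-equivalent path length (unit density) from the
body entry point to the voxel and ``dperp`` the 3-D distance from the voxel
centre to the beamlet axis. Parallel geometry keeps the box phantom's exact
four-fold symmetry, which gives the package a strong rotational oracle.

Gantry convention: 0 deg enters from the anterior (+y in the axial image),
angles increase clockwise viewed from the patient's feet; all beams are
coplanar (direction in the axial plane).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantoms import Phantom


# --------------------------------------------------------------------------
# candidate pool


@dataclass(frozen=True)
class CandidatePool:
    """Equally spaced coplanar candidate gantry angles covering [0, 360)."""

    resolution_deg: float
    angles: tuple[float, ...]

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def enumerate_candidates(resolution_deg: float) -> CandidatePool:
    """All gantry angles {0, r, 2r, ...} for a resolution r dividing 360."""
    r = float(resolution_deg)
    if r <= 0 or abs(360.0 / r - round(360.0 / r)) > 1e-9:
        raise ValueError(f"resolution {resolution_deg} does not divide 360")
    n = int(round(360.0 / r))
    return CandidatePool(resolution_deg=r, angles=tuple(k * r for k in range(n)))


def count_configurations(pool: CandidatePool, n_beams: int) -> int:
    """Size of the unordered n-beam configuration space, C(N, n)."""
    n_beams = int(n_beams)
    if not 1 <= n_beams <= pool.n_angles:
        raise ValueError(f"n_beams must lie in [1, {pool.n_angles}], got {n_beams}")
    return math.comb(pool.n_angles, n_beams)


def circular_difference(a: float, b: float) -> float:
    """Shortest angular distance between two gantry angles, in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def snap_to_pool(angle: float, pool: CandidatePool) -> float:
    """Nearest pool angle; exact ties resolved clockwise (increasing angle)."""
    angles = np.asarray(pool.angles)
    d = np.abs(angles - (angle % 360.0))
    d = np.minimum(d, 360.0 - d)
    best = d.min()
    tied = angles[np.isclose(d, best, rtol=0.0, atol=1e-9)]
    if tied.size == 1:
        return float(tied[0])
    # clockwise = the tied angle reached by moving in +angle direction
    forward = (tied - angle) % 360.0
    return float(tied[np.argmin(np.abs(forward - best))])


# --------------------------------------------------------------------------
# beam geometry


def beam_direction(gantry_angle_deg: float) -> np.ndarray:
    """Unit propagation vector of the beam (source -> isocenter)."""
    g = np.radians(gantry_angle_deg)
    return np.array([-np.sin(g), -np.cos(g), 0.0])


def beam_lateral_axes(gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """In-plane lateral axis and the slice axis spanning the isocenter plane."""
    g = np.radians(gantry_angle_deg)
    e1 = np.array([np.cos(g), -np.sin(g), 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return e1, e2


@dataclass(frozen=True)
class BeamletGrid:
    """Rectangular beamlet tiling of the target projection on the isocenter plane."""

    gantry_angle_deg: float
    beamlet_size_cm: float
    centers: np.ndarray = field(repr=False)  # (N_ray, 2) in (lateral, slice) cm
    n_lateral: int
    n_slice: int

    @property
    def n_beamlets(self) -> int:
        return int(self.centers.shape[0])


def beamlet_grid(phantom: Phantom, gantry_angle_deg: float,
                 beamlet_size_cm: float = 1.0) -> BeamletGrid:
    """Tile the union-of-targets projection with beamlets plus a one-beamlet margin.

    The projection is onto the plane through the isocenter perpendicular to
    the beam; its bounding box (voxel extents included) is expanded by one
    beamlet on every side and tiled with ``beamlet_size_cm`` squares centred
    on the box centre.
    """
    if beamlet_size_cm <= 0:
        raise ValueError("beamlet_size_cm must be positive")
    targets = phantom.targets
    if not targets:
        raise ValueError("phantom has no target structure")
    idx = np.unique(np.concatenate([t.voxels for t in targets]))
    pts = phantom.grid.voxel_centers(idx)
    e1, _ = beam_lateral_axes(gantry_angle_deg)
    s = pts @ e1
    t = pts[:, 2]
    vx, vy, vz = phantom.grid.voxel_size
    # projected footprint of one voxel onto the lateral axis
    foot_s = abs(e1[0]) * vx + abs(e1[1]) * vy
    width_s = (s.max() - s.min()) + foot_s
    width_t = (t.max() - t.min()) + vz
    b = float(beamlet_size_cm)
    n_s = int(np.ceil(width_s / b - 1e-9)) + 2
    n_t = int(np.ceil(width_t / b - 1e-9)) + 2
    c_s = (s.max() + s.min()) / 2.0
    c_t = (t.max() + t.min()) / 2.0
    ss = c_s + (np.arange(n_s) - (n_s - 1) / 2.0) * b
    tt = c_t + (np.arange(n_t) - (n_t - 1) / 2.0) * b
    S, T = np.meshgrid(ss, tt, indexing="ij")
    centers = np.column_stack([S.ravel(), T.ravel()])
    return BeamletGrid(
        gantry_angle_deg=float(gantry_angle_deg),
        beamlet_size_cm=b,
        centers=centers,
        n_lateral=n_s,
        n_slice=n_t,
    )


# --------------------------------------------------------------------------
# dose-influence matrix


@dataclass(frozen=True)
class KernelParams:
    """Pencil-kernel parameters: attenuation, lateral spread, sparsity cutoff."""

    mu_per_cm: float = 0.04
    sigma_cm: float = 0.5
    cutoff: float = 1e-4

    def __post_init__(self):
        if self.mu_per_cm <= 0:
            raise ValueError("mu_per_cm must be positive")
        if self.sigma_cm <= 0:
            raise ValueError("sigma_cm must be positive")
        if not 0 <= self.cutoff < 1:
            raise ValueError("cutoff must lie in [0, 1)")


def pencil_kernel(depth_cm, dperp_cm, params: KernelParams):
    """Closed-form kernel value: depth attenuation times lateral Gaussian."""
    depth_cm = np.asarray(depth_cm, dtype=float)
    dperp_cm = np.asarray(dperp_cm, dtype=float)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * params.sigma_cm)
    return np.exp(-params.mu_per_cm * depth_cm) * np.exp(
        -(dperp_cm**2) / (2.0 * params.sigma_cm**2)
    ) * norm


def radiological_depth(phantom: Phantom, gantry_angle_deg: float,
                       step_factor: float = 0.5) -> np.ndarray:
    """Water-equivalent depth of every body voxel along the beam direction.

    Ray-marches upstream from each voxel centre at ``step_factor`` times the
    smallest voxel edge, accumulating path length through body voxels
    (uniform unit density). Returns one depth (cm) per body voxel, in body
    voxel order.
    """
    d = beam_direction(gantry_angle_deg)
    grid = phantom.grid
    body_idx = phantom.body.voxels
    pts = grid.voxel_centers(body_idx)
    body_mask = grid.mask_from_indices(body_idx)
    step = step_factor * min(grid.voxel_size)
    origin = np.array(grid.origin)
    vs = np.array(grid.voxel_size)
    shape = np.array(grid.shape)
    # beams are coplanar, so the upstream path never exceeds the in-plane diagonal
    ext = shape * vs
    max_path = float(np.hypot(ext[0], ext[1])) + 2 * step
    depth = np.zeros(len(pts))
    tau = step / 2.0
    while tau < max_path:
        q = pts - d * tau
        ijk = np.rint((q - origin) / vs).astype(np.int64)
        valid = np.all((ijk >= 0) & (ijk < shape), axis=1)
        if not valid.any():
            break
        inside = np.zeros(len(pts), dtype=bool)
        vi = ijk[valid]
        inside[valid] = body_mask[vi[:, 0], vi[:, 1], vi[:, 2]]
        depth[inside] += step
        tau += step
    return depth


@dataclass(frozen=True)
class DoseInfluenceMatrix:
    """Sparse map from beamlet fluence weights to dose in body voxels (Gy/unit)."""

    matrix: sp.csr_matrix = field(repr=False)  # (n_body_voxels, n_beamlets)
    gantry_angle_deg: float
    beamlets: BeamletGrid

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def compute_dose_matrix(
    phantom: Phantom,
    grid: BeamletGrid,
    kernel_params: KernelParams | None = None,
    depth: np.ndarray | None = None,
) -> DoseInfluenceMatrix:
    """Evaluate the pencil kernel at every body voxel for every beamlet.

    Entries below ``cutoff`` times their column maximum are dropped to keep
    the matrix sparse; voxels outside the body carry no rows at all (the
    matrix is indexed over body voxels). A beamlet whose lateral profile
    misses the body yields an all-zero column, kept with a warning (its
    fluence simply optimizes to zero).
    """
    kp = kernel_params or KernelParams()
    if depth is None:
        depth = radiological_depth(phantom, grid.gantry_angle_deg)
    pts = phantom.grid.voxel_centers(phantom.body.voxels)
    e1, _ = beam_lateral_axes(grid.gantry_angle_deg)
    s = pts @ e1
    t = pts[:, 2]
    atten = np.exp(-kp.mu_per_cm * depth)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * kp.sigma_cm)
    d2 = (s[:, None] - grid.centers[None, :, 0]) ** 2 + (
        t[:, None] - grid.centers[None, :, 1]
    ) ** 2
    K = atten[:, None] * np.exp(-d2 / (2.0 * kp.sigma_cm**2)) * norm
    colmax = K.max(axis=0)
    K[K < kp.cutoff * colmax[None, :]] = 0.0
    n_zero = int(np.count_nonzero(colmax == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} beamlet(s) at gantry {grid.gantry_angle_deg} deg deposit no "
            "dose in the body; their fluence will optimize to zero",
            stacklevel=2,
        )
    return DoseInfluenceMatrix(
        matrix=sp.csr_matrix(K),
        gantry_angle_deg=grid.gantry_angle_deg,
        beamlets=grid,
    )


def compute_dose(dose_matrices, fluence_maps) -> np.ndarray:
    """Total dose D_i = sum over beams and beamlets of K_im x_m (body voxels)."""
    if len(dose_matrices) != len(fluence_maps):
        raise ValueError("need exactly one fluence map per dose matrix")
    dose = None
    for K, x in zip(dose_matrices, fluence_maps):
        M = K.matrix if isinstance(K, DoseInfluenceMatrix) else K
        x = np.asarray(x, dtype=float)
        if M.shape[1] != x.shape[0]:
            raise ValueError(
                f"fluence length {x.shape[0]} does not match {M.shape[1]} beamlets"
            )
        contrib = M @ x
        dose = contrib if dose is None else dose + contrib
    return np.asarray(dose)


class DoseMatrixCache:
    """Per-angle dose-influence matrices, computed once per phantom/kernel."""

    def __init__(self, phantom: Phantom, kernel_params: KernelParams | None = None,
                 beamlet_size_cm: float = 1.0):
        self.phantom = phantom
        self.kernel_params = kernel_params or KernelParams()
        self.beamlet_size_cm = beamlet_size_cm
        self._matrices: dict[float, DoseInfluenceMatrix] = {}

    def get(self, gantry_angle_deg: float) -> DoseInfluenceMatrix:
        key = float(gantry_angle_deg) % 360.0
        if key not in self._matrices:
            grid = beamlet_grid(self.phantom, key, self.beamlet_size_cm)
            self._matrices[key] = compute_dose_matrix(self.phantom, grid,
                                                      self.kernel_params)
        return self._matrices[key]

    def get_config(self, angles) -> list[DoseInfluenceMatrix]:
        return [self.get(a) for a in angles]
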