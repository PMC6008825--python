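"""Synthetic voxel phantoms for beam-angle optimization experiments.

Three presets mirror the standard benchmark geometries used in coplanar
IMRT planning studies: a box phantom with a centred cubic PTV (whose
optimal four-beam configuration is equispaced by symmetry), a TG-119-like
cylinder with a C-shaped target wrapped around a central core organ at
risk, and a prostate-like case with two nested target volumes flanked by
bladder and rectum.

Conventions
-----------
* The grid is axis-aligned; coordinates are in cm; the machine isocenter
  sits at the geometric centre of the grid. The axial (gantry-rotation)
  plane is (x, y); z is the slice axis.
* A voxel belongs to a structure iff its *centre* lies inside the analytic
  shape (center sampling, no partial volumes), which makes every preset
  deterministic and countable in closed form.
* Structures store sorted linear voxel indices raveled in C order over
  (nx, ny, nz).
* Where analytic shapes overlap, targets claim the voxel over organs at
  risk (the usual PTV-priority boolean used in planning systems).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

ROLE_TARGET = "target"
ROLE_OAR = "oar"
ROLE_BODY = "body"
_ROLES = (ROLE_TARGET, ROLE_OAR, ROLE_BODY)


def _as_triple(v) -> tuple[float, float, float]:
    if np.isscalar(v):
        return (float(v), float(v), float(v))
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 sequence, got {v!r}")
    return t


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid with the isocenter at its geometric centre."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", _as_triple(self.voxel_size))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three integers >= 1, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def origin(self) -> tuple[float, float, float]:
        """Centre of voxel (0, 0, 0) in cm (isocenter = grid centre)."""
        return tuple(-(n - 1) / 2.0 * v for n, v in zip(self.shape, self.voxel_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        v = self.voxel_size[axis]
        return (np.arange(n) - (n - 1) / 2.0) * v

    def voxel_centers(self, linear_indices: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates in cm."""
        if linear_indices is None:
            linear_indices = np.arange(self.n_voxels)
        ijk = np.column_stack(np.unravel_index(np.asarray(linear_indices), self.shape))
        origin = np.array(self.origin)
        return origin + ijk * np.array(self.voxel_size)

    def ravel(self, i, j, k) -> np.ndarray:
        return np.ravel_multi_index((i, j, k), self.shape)

    def mask_from_indices(self, linear_indices: np.ndarray) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask.flat[np.asarray(linear_indices)] = True
        return mask


@dataclass(frozen=True)
class Structure:
    """Named voxel set with a planning role (target / oar / body)."""

    name: str
    role: str
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        v = np.unique(np.asarray(self.voxels, dtype=np.int64))
        if v.size == 0:
            raise ValueError(f"structure {self.name!r} has no voxels")
        if v.min() < 0:
            raise ValueError(f"structure {self.name!r} has negative voxel indices")
        object.__setattr__(self, "voxels", v)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)


@dataclass(frozen=True)
class Phantom:
    grid: VoxelGrid
    structures: tuple[Structure, ...]

    def __post_init__(self):
        object.__setattr__(self, "structures", tuple(self.structures))
        bodies = [s for s in self.structures if s.role == ROLE_BODY]
        if len(bodies) != 1:
            raise ValueError(f"phantom must have exactly one body structure, got {len(bodies)}")
        body = set(bodies[0].voxels.tolist())
        n = self.grid.n_voxels
        seen: set[str] = set()
        claimed: set[int] = set()
        for s in self.structures:
            if s.name in seen:
                raise ValueError(f"duplicate structure name {s.name!r}")
            seen.add(s.name)
            if s.voxels.max() >= n:
                raise ValueError(f"structure {s.name!r} has voxels outside the grid")
            if s.role != ROLE_BODY:
                vox = set(s.voxels.tolist())
                if not vox <= body:
                    raise ValueError(f"structure {s.name!r} is not contained in the body")
                if vox & claimed:
                    raise ValueError(f"structure {s.name!r} overlaps another target/OAR")
                claimed |= vox

    @property
    def body(self) -> Structure:
        return next(s for s in self.structures if s.role == ROLE_BODY)

    @property
    def targets(self) -> tuple[Structure, ...]:
        return tuple(s for s in self.structures if s.role == ROLE_TARGET)

    @property
    def oars(self) -> tuple[Structure, ...]:
        return tuple(s for s in self.structures if s.role == ROLE_OAR)

    def structure(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}")

    def structure_names(self) -> list[str]:
        return [s.name for s in self.structures]

    def body_rows(self, structure: Structure | str) -> np.ndarray:
        """Positions of a structure's voxels inside the sorted body voxel list.

        Dose vectors and dose-influence matrices are indexed over body
        voxels only; this maps a structure onto those rows.
        """
        if isinstance(structure, str):
            structure = self.structure(structure)
        body = self.body.voxels
        rows = np.searchsorted(body, structure.voxels)
        if rows.max(initial=-1) >= body.size or not np.array_equal(body[rows], structure.voxels):
            raise ValueError(f"structure {structure.name!r} has voxels outside the body")
        return rows

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(repr((self.grid.shape, self.grid.voxel_size)).encode())
        for s in self.structures:
            h.update(s.name.encode())
            h.update(s.role.encode())
            h.update(s.voxels.tobytes())
        return h.hexdigest()


def _grid_for(half_widths_cm, voxel_size) -> VoxelGrid:
    vs = _as_triple(voxel_size)
    shape = tuple(max(1, int(round(2.0 * hw / v))) for hw, v in zip(half_widths_cm, vs))
    return VoxelGrid(shape=shape, voxel_size=vs)


def make_box_phantom(
    body_half_width_cm: float = 10.0,
    ptv_half_width_cm: float = 2.0,
    voxel_size_cm=0.5,
    body_half_length_cm: float = 5.0,
    ptv_half_length_cm: float = 0.5,
) -> Phantom:
    """Square-section body with a centred cubic PTV.

    The axial cross-section of both body and PTV is a square centred on
    the isocenter, so the phantom is exactly invariant under 90-degree
    rotations about the grid centre and its optimal four-beam
    configuration is equispaced. ``*_half_length_cm`` control the z
    (slice-axis) extent; the default keeps the phantom thin in z.
    """
    if not 0 < ptv_half_width_cm < body_half_width_cm:
        raise ValueError("require 0 < ptv_half_width_cm < body_half_width_cm")
    if not 0 < ptv_half_length_cm <= body_half_length_cm:
        raise ValueError("require 0 < ptv_half_length_cm <= body_half_length_cm")
    vs = _as_triple(voxel_size_cm)
    if vs[0] != vs[1]:
        raise ValueError("box phantom requires square in-plane voxels (vx == vy)")
    grid = _grid_for((body_half_width_cm, body_half_width_cm, body_half_length_cm), vs)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    body = (np.abs(X) < body_half_width_cm) & (np.abs(Y) < body_half_width_cm) & (
        np.abs(Z) < body_half_length_cm
    )
    ptv = (np.abs(X) < ptv_half_width_cm) & (np.abs(Y) < ptv_half_width_cm) & (
        np.abs(Z) < ptv_half_length_cm
    )
    if not ptv.any():
        raise ValueError("PTV is empty at this voxel size")
    return Phantom(
        grid=grid,
        structures=(
            Structure("PTV", ROLE_TARGET, np.flatnonzero(ptv)),
            Structure("Body", ROLE_BODY, np.flatnonzero(body)),
        ),
    )


def make_cshape_phantom(
    outer_radius_cm: float = 4.0,
    inner_radius_cm: float = 1.5,
    core_radius_cm: float = 1.0,
    gap_deg: float = 90.0,
    voxel_size_cm=0.25,
    body_radius_cm: float | None = None,
    body_half_length_cm: float = 1.0,
    structure_half_length_cm: float | None = None,
) -> Phantom:
    """Cylindrical body with a C-shaped annular PTV around a core OAR.

    The PTV occupies the annulus ``inner <= r <= outer`` minus an angular
    gap of ``gap_deg`` centred on the anterior (+y) direction; the core is
    a central cylinder of ``core_radius_cm``. Geometry of the classic
    concave-target commissioning benchmark.
    """
    if not 0 < core_radius_cm < inner_radius_cm < outer_radius_cm:
        raise ValueError("require 0 < core_radius < inner_radius < outer_radius")
    if not 0 <= gap_deg < 360:
        raise ValueError("gap_deg must lie in [0, 360)")
    if body_radius_cm is None:
        body_radius_cm = outer_radius_cm + 2.0
    if body_radius_cm <= outer_radius_cm:
        raise ValueError("body radius must exceed the PTV outer radius")
    if structure_half_length_cm is None:
        structure_half_length_cm = body_half_length_cm
    grid = _grid_for((body_radius_cm, body_radius_cm, body_half_length_cm), voxel_size_cm)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    R = np.hypot(X, Y)
    in_slab = np.abs(Z) < structure_half_length_cm
    body = (R <= body_radius_cm) & (np.abs(Z) < body_half_length_cm)
    # azimuth measured from +y (anterior), increasing clockwise like the gantry
    phi = np.degrees(np.arctan2(X, Y)) % 360.0
    away_from_gap = np.minimum(phi, 360.0 - phi) >= gap_deg / 2.0
    ptv = (R >= inner_radius_cm) & (R <= outer_radius_cm) & away_from_gap & in_slab
    core = (R <= core_radius_cm) & in_slab
    if not ptv.any():
        raise ValueError("PTV is empty for these radii / voxel size")
    if not core.any():
        raise ValueError("core is empty for these radii / voxel size")
    return Phantom(
        grid=grid,
        structures=(
            Structure("PTV", ROLE_TARGET, np.flatnonzero(ptv)),
            Structure("core", ROLE_OAR, np.flatnonzero(core)),
            Structure("Body", ROLE_BODY, np.flatnonzero(body)),
        ),
    )


@dataclass(frozen=True)
class ProstateParams:
    """Geometry of the prostate-like preset (all lengths in cm).

    Two nested ellipsoidal targets (boost volume inside the larger
    prescription volume), an anterior-superior bladder ellipsoid and a
    posterior rectum cylinder, inside a rectangular body.
    """

    body_half_widths: tuple[float, float, float] = (10.0, 10.0, 5.0)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    ptv68_radii: tuple[float, float, float] = (2.5, 2.5, 2.0)
    ptv56_radii: tuple[float, float, float] = (4.0, 4.0, 3.0)
    bladder_center: tuple[float, float, float] = (0.0, 6.0, 1.0)
    bladder_radii: tuple[float, float, float] = (2.5, 2.2, 2.0)
    rectum_center_y: float = -5.5
    rectum_radius: float = 1.5
    rectum_half_length: float = 4.0


def make_prostate_phantom(params: ProstateParams | None = None) -> Phantom:
    """Prostate-like phantom: PTV 56 / PTV 68 / Bladder / Rectum / Body.

    The boost target (PTV 68) is an ellipsoid at the isocenter; PTV 56 is
    the surrounding ellipsoidal shell (the two target structures are
    disjoint voxel sets). Targets take precedence over OARs where the
    analytic shapes touch.
    """
    p = params or ProstateParams()
    grid = _grid_for(p.body_half_widths, p.voxel_size)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    def ellipsoid(center, radii):
        cx, cy, cz = center
        rx, ry, rz = radii
        return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0

    body = np.ones(grid.shape, dtype=bool)  # rectangular body fills the grid
    ptv68 = ellipsoid((0, 0, 0), p.ptv68_radii)
    ptv56 = ellipsoid((0, 0, 0), p.ptv56_radii) & ~ptv68
    bladder = ellipsoid(p.bladder_center, p.bladder_radii)
    rectum = (np.hypot(X, Y - p.rectum_center_y) <= p.rectum_radius) & (
        np.abs(Z) < p.rectum_half_length
    )
    target_union = ptv68 | ptv56
    if (bladder & ptv68).any():
        raise ValueError("bladder overlaps the boost target; adjust geometry parameters")
    bladder &= ~target_union
    rectum &= ~target_union
    if (bladder & rectum).any():
        raise ValueError("bladder and rectum overlap; adjust geometry parameters")
    for name, mask in (("PTV 56", ptv56), ("PTV 68", ptv68),
                       ("Bladder", bladder), ("Rectum", rectum)):
        if not mask.any():
            raise ValueError(f"{name} is empty for these parameters")
    return Phantom(
        grid=grid,
        structures=(
            Structure("PTV 56", ROLE_TARGET, np.flatnonzero(ptv56)),
            Structure("PTV 68", ROLE_TARGET, np.flatnonzero(ptv68)),
            Structure("Bladder", ROLE_OAR, np.flatnonzero(bladder)),
            Structure("Rectum", ROLE_OAR, np.flatnonzero(rectum)),
            Structure("Body", ROLE_BODY, np.flatnonzero(body)),
        ),
    )


_PRESETS = {
    "box": make_box_phantom,
    "tg119": make_cshape_phantom,
    "prostate": make_prostate_phantom,
}


def make_preset(name: str, **kwargs) -> Phantom:
    """Build one of the bundled phantom presets: box, tg119, prostate."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown phantom preset {name!r}; choose from {sorted(_PRESETS)}")
    return builder(**kwargs)
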