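"""Fluence-map optimization: quadratic one-sided penalties, projected CG.

For a fixed set of beams the plan quality is the minimum of

    F(x) = sum_targets p * (D_i(x) - D_pres)^2
         + sum_oars    p * max(D_i(x) - D_max, 0)^2,     D = K x,  x >= 0,

over nonnegative beamlet weights x. Target voxels are penalized for any
deviation from the prescribed dose; organs at risk (and the body) only for
exceeding their maximum-dose threshold, so satisfied constraints contribute
nothing. The objective is convex and continuously differentiable; the
minimum value F_opt is the score a beam configuration receives in the
outer beam-angle search.

The solver is a Polak-Ribiere nonlinear conjugate gradient with steps from
the local quadratic model, Armijo-style backtracking, and projection onto
x >= 0; the CG direction resets to projected steepest descent whenever the
active set changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dose_engine import DoseInfluenceMatrix
from .phantoms import Phantom, ROLE_BODY, ROLE_TARGET

SQUARE_DEVIATION = "square_deviation"
SQUARE_OVERDOSING = "square_overdosing"


@dataclass(frozen=True)
class ObjectiveTerm:
    """One per-structure penalty term of the plan objective."""

    structure: str
    kind: str  # square_deviation (targets) or square_overdosing (OAR/body)
    penalty: float
    dose_gy: float  # prescribed dose for targets, maximum dose for OARs

    def __post_init__(self):
        if self.kind not in (SQUARE_DEVIATION, SQUARE_OVERDOSING):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.dose_gy <= 0:
            raise ValueError("dose level must be positive")


@dataclass(frozen=True)
class Prescription:
    terms: tuple[ObjectiveTerm, ...]

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if not any(t.kind == SQUARE_DEVIATION for t in self.terms):
            raise ValueError("prescription needs at least one target (square_deviation) term")

    def validate(self, phantom: Phantom) -> None:
        names = set(phantom.structure_names())
        for t in self.terms:
            if t.structure not in names:
                raise KeyError(f"prescription references missing structure {t.structure!r}")
            role = phantom.structure(t.structure).role
            if t.kind == SQUARE_DEVIATION and role != ROLE_TARGET:
                raise ValueError(f"square_deviation on non-target structure {t.structure!r}")
            if t.kind == SQUARE_OVERDOSING and role == ROLE_TARGET:
                raise ValueError(f"square_overdosing on target structure {t.structure!r}")

    def target_dose(self, structure: str) -> float:
        for t in self.terms:
            if t.structure == structure and t.kind == SQUARE_DEVIATION:
                return t.dose_gy
        raise KeyError(f"no prescribed (target) dose for structure {structure!r}")


def box_prescription() -> Prescription:
    """Box benchmark: PTV 30 Gy (p=1000), body kept below 20 Gy (p=100)."""
    return Prescription((
        ObjectiveTerm("PTV", SQUARE_DEVIATION, 1000.0, 30.0),
        ObjectiveTerm("Body", SQUARE_OVERDOSING, 100.0, 20.0),
    ))


def tg119_prescription() -> Prescription:
    """Concave-target benchmark: PTV 50 Gy (p=1000), core <= 30 Gy (p=300), body <= 30 Gy (p=100)."""
    return Prescription((
        ObjectiveTerm("PTV", SQUARE_DEVIATION, 1000.0, 50.0),
        ObjectiveTerm("core", SQUARE_OVERDOSING, 300.0, 30.0),
        ObjectiveTerm("Body", SQUARE_OVERDOSING, 100.0, 30.0),
    ))


def prostate_prescription() -> Prescription:
    """Prostate case: two targets (56 / 68 Gy), bladder and rectum <= 45 Gy, body <= 70 Gy."""
    return Prescription((
        ObjectiveTerm("PTV 56", SQUARE_DEVIATION, 1000.0, 56.0),
        ObjectiveTerm("PTV 68", SQUARE_DEVIATION, 1000.0, 68.0),
        ObjectiveTerm("Bladder", SQUARE_OVERDOSING, 300.0, 45.0),
        ObjectiveTerm("Rectum", SQUARE_OVERDOSING, 300.0, 45.0),
        ObjectiveTerm("Body", SQUARE_OVERDOSING, 100.0, 70.0),
    ))


_PRESCRIPTION_PRESETS = {
    "box": box_prescription,
    "tg119": tg119_prescription,
    "prostate": prostate_prescription,
}


def get_prescription(name: str) -> Prescription:
    try:
        return _PRESCRIPTION_PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown prescription preset {name!r}; choose from {sorted(_PRESCRIPTION_PRESETS)}"
        )


@dataclass(frozen=True)
class FmoSolverParams:
    max_iters: int = 200
    rel_tol: float = 1e-6
    restart_on_active_set_change: bool = True

    def __post_init__(self):
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass
class FmoResult:
    fluence_maps: list[np.ndarray]
    objective: float
    trace: np.ndarray = field(repr=False)
    n_iterations: int = 0
    converged: bool = False


# --------------------------------------------------------------------------
# compiled terms: (body-row indices, is_target, penalty, dose level)


def _compile_terms(prescription: Prescription, phantom: Phantom,
                   body_excludes_targets: bool = True):
    prescription.validate(phantom)
    target_rows = [phantom.body_rows(t.structure) for t in prescription.terms
                   if t.kind == SQUARE_DEVIATION]
    all_target_rows = (np.unique(np.concatenate(target_rows))
                       if target_rows else np.empty(0, dtype=np.int64))
    compiled = []
    for t in prescription.terms:
        rows = phantom.body_rows(t.structure)
        if (
            body_excludes_targets
            and t.kind == SQUARE_OVERDOSING
            and phantom.structure(t.structure).role == ROLE_BODY
        ):
            rows = np.setdiff1d(rows, all_target_rows, assume_unique=True)
            if rows.size == 0:
                continue
        compiled.append((rows, t.kind == SQUARE_DEVIATION, t.penalty, t.dose_gy))
    return compiled


def objective_value(dose: np.ndarray, prescription: Prescription, phantom: Phantom,
                    body_excludes_targets: bool = True) -> float:
    """Plan objective F for a dose vector over body voxels."""
    dose = np.asarray(dose, dtype=float)
    if dose.shape[0] != phantom.body.n_voxels:
        raise ValueError("dose vector must cover all body voxels")
    terms = _compile_terms(prescription, phantom, body_excludes_targets)
    return _objective_from_terms(dose, terms)


def _objective_from_terms(dose: np.ndarray, terms) -> float:
    f = 0.0
    for rows, is_target, p, level in terms:
        if is_target:
            r = dose[rows] - level
        else:
            r = np.maximum(dose[rows] - level, 0.0)
        f += p * float(r @ r)
    return f


def _residual_weighted(dose: np.ndarray, terms) -> np.ndarray:
    """Per-voxel weighted residual w with grad F = 2 K^T w."""
    w = np.zeros_like(dose)
    for rows, is_target, p, level in terms:
        if is_target:
            np.add.at(w, rows, p * (dose[rows] - level))
        else:
            np.add.at(w, rows, p * np.maximum(dose[rows] - level, 0.0))
    return w


def _active_weight(dose: np.ndarray, terms) -> np.ndarray:
    """Per-voxel curvature weight of the local quadratic model."""
    w = np.zeros_like(dose)
    for rows, is_target, p, level in terms:
        if is_target:
            np.add.at(w, rows, p)
        else:
            active = rows[dose[rows] > level]
            np.add.at(w, active, p)
    return w


def _stack(dose_matrices) -> tuple[sp.csr_matrix, list[int]]:
    mats = [K.matrix if isinstance(K, DoseInfluenceMatrix) else sp.csr_matrix(K)
            for K in dose_matrices]
    sizes = [M.shape[1] for M in mats]
    return sp.hstack(mats, format="csr"), sizes


def objective_gradient(fluence_maps, dose_matrices, prescription: Prescription,
                       phantom: Phantom,
                       body_excludes_targets: bool = True) -> list[np.ndarray]:
    """Analytic gradient of F with respect to each beam's fluence map."""
    if len(fluence_maps) != len(dose_matrices):
        raise ValueError("need one fluence map per dose matrix")
    K, sizes = _stack(dose_matrices)
    x = np.concatenate([np.asarray(f, dtype=float) for f in fluence_maps])
    if x.shape[0] != K.shape[1]:
        raise ValueError("fluence lengths do not match beamlet counts")
    terms = _compile_terms(prescription, phantom, body_excludes_targets)
    dose = K @ x
    g = 2.0 * (K.T @ _residual_weighted(dose, terms))
    return list(np.split(g, np.cumsum(sizes)[:-1]))


def solve_fmo(
    dose_matrices,
    prescription: Prescription,
    phantom: Phantom,
    solver_params: FmoSolverParams | None = None,
    x0=None,
    body_excludes_targets: bool = True,
) -> FmoResult:
    """Minimize the plan objective over nonnegative beamlet weights.

    Returns the per-beam fluence maps, the optimal objective F_opt used to
    score the beam configuration, and the (non-increasing) objective trace.
    Starts from x = 0 unless ``x0`` is given.
    """
    params = solver_params or FmoSolverParams()
    if len(dose_matrices) == 0:
        raise ValueError("need at least one beam")
    K, sizes = _stack(dose_matrices)
    terms = _compile_terms(prescription, phantom, body_excludes_targets)
    target_rows = np.unique(np.concatenate([rows for rows, is_t, _, _ in terms if is_t]))
    if K[target_rows].count_nonzero() == 0:
        raise ValueError("configuration cannot irradiate target (all-zero dose matrix rows)")

    n = K.shape[1]
    if x0 is None:
        x = np.zeros(n)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape[0] != n or (x < 0).any():
            raise ValueError("x0 must be a nonnegative vector matching total beamlet count")

    dose = K @ x
    f = _objective_from_terms(dose, terms)
    trace = [f]
    pg_prev = None
    d = None
    active_prev = x <= 0.0
    stall = 0
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        g = 2.0 * (K.T @ _residual_weighted(dose, terms))
        pg = g.copy()
        pg[(x <= 0.0) & (g > 0.0)] = 0.0  # components blocked by the bound
        gnorm2 = float(pg @ pg)
        if gnorm2 <= 1e-24 * max(1.0, f):
            converged = True
            break
        active = x <= 0.0
        restart = (
            d is None
            or (params.restart_on_active_set_change and not np.array_equal(active, active_prev))
        )
        if restart:
            d = -pg
        else:
            beta = max(0.0, float(pg @ (pg - pg_prev)) / float(pg_prev @ pg_prev))
            d = -pg + beta * d
            if float(d @ g) >= 0.0:  # not a descent direction: reset
                d = -pg
        pg_prev = pg
        active_prev = active

        # step length from the local quadratic model along d
        Kd = K @ d
        curv = 2.0 * float(Kd @ (_active_weight(dose, terms) * Kd))
        gd = float(g @ d)
        alpha = -gd / curv if curv > 0 else 1.0
        if alpha <= 0:
            alpha = 1.0
        # backtrack (hinge activation can make the model step overshoot)
        f_new = f
        for _ in range(40):
            x_try = np.maximum(x + alpha * d, 0.0)
            dose_try = K @ x_try
            f_try = _objective_from_terms(dose_try, terms)
            if f_try <= f:
                x, dose, f_new = x_try, dose_try, f_try
                break
            alpha *= 0.5
        if f_new >= f and trace[-1] == f:
            # no progress possible along this direction
            if restart:
                converged = True
                break
            d = None  # force steepest-descent restart next pass
            trace.append(f)
            continue
        rel = abs(f - f_new) / max(abs(f), 1e-300)
        f = f_new
        trace.append(f)
        stall = stall + 1 if rel < params.rel_tol else 0
        if stall >= 3:
            converged = True
            break

    maps = list(np.split(x, np.cumsum(sizes)[:-1]))
    return FmoResult(
        fluence_maps=maps,
        objective=f,
        trace=np.asarray(trace),
        n_iterations=it,
        converged=converged,
    )
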