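"""Serialization, run configuration and the end-to-end planning pipeline.

File formats are deliberately plain: phantom voxel lists as CSV plus a JSON
grid header, dose-influence matrices as MatrixMarket ``.mtx`` with a JSON
sidecar, fluence maps and DVH curves as CSV, results and reports as JSON,
run configuration as YAML or JSON. Every JSON artifact is written with
sorted keys and no timestamps, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import bao as _bao
from .dose_engine import (
    BeamletGrid,
    CandidatePool,
    DoseInfluenceMatrix,
    DoseMatrixCache,
    KernelParams,
    compute_dose,
    enumerate_candidates,
    snap_to_pool,
)
from .evaluation import PlanIndices, compare_plans, cumulative_dvh, plan_report
from .fmo import FmoSolverParams, Prescription, get_prescription, solve_fmo
from .phantoms import Phantom, Structure, VoxelGrid, make_preset

log = logging.getLogger("imrtbao")


# --------------------------------------------------------------------------
# phantom serialization: CSV of (name, role, i, j, k) + JSON grid header


def save_phantom(phantom: Phantom, csv_path, header_path) -> None:
    records = []
    for s in phantom.structures:
        i, j, k = np.unravel_index(s.voxels, phantom.grid.shape)
        records.append(pd.DataFrame({
            "name": s.name, "role": s.role, "i": i, "j": j, "k": k,
        }))
    pd.concat(records, ignore_index=True).to_csv(csv_path, index=False)
    header = {
        "shape": list(phantom.grid.shape),
        "voxel_size_cm": list(phantom.grid.voxel_size),
    }
    _write_json(header, header_path)


def load_phantom(csv_path, header_path) -> Phantom:
    with open(header_path) as fh:
        header = json.load(fh)
    grid = VoxelGrid(shape=tuple(header["shape"]),
                     voxel_size=tuple(header["voxel_size_cm"]))
    df = pd.read_csv(csv_path)
    structures = []
    for (name, role), g in df.groupby(["name", "role"], sort=False):
        lin = np.ravel_multi_index(
            (g["i"].to_numpy(), g["j"].to_numpy(), g["k"].to_numpy()), grid.shape
        )
        structures.append(Structure(str(name), str(role), lin))
    return Phantom(grid=grid, structures=tuple(structures))


# --------------------------------------------------------------------------
# dose matrices: MatrixMarket + JSON sidecar


def save_dose_matrix(dim: DoseInfluenceMatrix, mtx_path, sidecar_path,
                     kernel_params: KernelParams | None = None) -> None:
    scipy.io.mmwrite(str(mtx_path), dim.matrix)
    sidecar = {
        "gantry_angle_deg": dim.gantry_angle_deg,
        "beamlet_size_cm": dim.beamlets.beamlet_size_cm,
        "beamlet_centers": dim.beamlets.centers.tolist(),
        "n_lateral": dim.beamlets.n_lateral,
        "n_slice": dim.beamlets.n_slice,
    }
    if kernel_params is not None:
        sidecar["kernel_params"] = asdict(kernel_params)
    _write_json(sidecar, sidecar_path)


def load_dose_matrix(mtx_path, sidecar_path) -> DoseInfluenceMatrix:
    M = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    with open(sidecar_path) as fh:
        sc = json.load(fh)
    grid = BeamletGrid(
        gantry_angle_deg=sc["gantry_angle_deg"],
        beamlet_size_cm=sc["beamlet_size_cm"],
        centers=np.asarray(sc["beamlet_centers"], dtype=float),
        n_lateral=sc["n_lateral"],
        n_slice=sc["n_slice"],
    )
    return DoseInfluenceMatrix(matrix=M, gantry_angle_deg=sc["gantry_angle_deg"],
                               beamlets=grid)


# --------------------------------------------------------------------------
# fluence, DVH, reports


def save_fluence(angles, fluence_maps, grids, path) -> None:
    """CSV of (beam angle, beamlet row, beamlet col, weight)."""
    frames = []
    for angle, x, grid in zip(angles, fluence_maps, grids):
        rows, cols = np.unravel_index(np.arange(len(x)), (grid.n_lateral, grid.n_slice))
        frames.append(pd.DataFrame({
            "gantry_angle_deg": angle, "row": rows, "col": cols, "weight": x,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_fluence(path) -> tuple[list[float], list[np.ndarray]]:
    df = pd.read_csv(path)
    angles, maps = [], []
    for angle, g in df.groupby("gantry_angle_deg", sort=True):
        angles.append(float(angle))
        maps.append(g["weight"].to_numpy())
    return angles, maps


def save_dvh(curves, path) -> None:
    frames = [
        pd.DataFrame({
            "structure": c.structure,
            "dose_gy": c.dose_edges,
            "volume_pct": c.volume_fraction,
        })
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# equispaced baseline


def equispaced_configuration(n_beams: int, start_angle: float,
                             pool: CandidatePool) -> tuple[float, ...]:
    """Uniformly spaced beams from a start angle, snapped onto the pool.

    Angles start + k*(360/n) are snapped to the nearest pool angle (exact
    ties resolved clockwise); duplicates after snapping are repaired to the
    nearest unused pool angle.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    raw = [snap_to_pool(start_angle + k * 360.0 / n_beams, pool) for k in range(n_beams)]
    return _bao._repair_duplicates(raw, pool)


# --------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Everything needed to reproduce one optimal-vs-equispaced experiment."""

    phantom: str = "box"  # preset name
    prescription: str | None = None  # preset name; defaults to the phantom preset
    resolution_deg: float = 10.0
    n_beams: int = 4
    eval_budget: int = 150
    population_size: int = 30
    refset_size: int = 10
    seed: int = 1
    equispaced_start_deg: float = 0.0
    beamlet_size_cm: float = 1.0
    kernel: dict = field(default_factory=dict)
    fmo: dict = field(default_factory=dict)
    phantom_kwargs: dict = field(default_factory=dict)
    out_dir: str = "bao_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def resolved(self) -> dict:
        d = asdict(self)
        d["prescription"] = self.prescription or self.phantom
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Generate phantom -> dose matrices -> BAO -> evaluate optimal vs equispaced.

    Writes all artifacts under ``config.out_dir`` and returns a summary dict
    (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(config.resolved(), out / "config.resolved.json")

    log.info("stage 1/4: phantom preset %r", config.phantom)
    phantom = make_preset(config.phantom, **config.phantom_kwargs)
    save_phantom(phantom, out / "phantom.csv", out / "phantom.json")

    prescription = get_prescription(config.prescription or config.phantom)
    pool = enumerate_candidates(config.resolution_deg)
    kernel = KernelParams(**config.kernel)
    solver = FmoSolverParams(**config.fmo)
    cache = _bao.ScoreCache(
        phantom, prescription,
        kernel_params=kernel, solver_params=solver,
        beamlet_size_cm=config.beamlet_size_cm,
    )

    log.info("stage 2/4: scatter search (%d beams, %d candidates, budget %d)",
             config.n_beams, pool.n_angles, config.eval_budget)
    params = _bao.ScatterSearchParams(
        population_size=config.population_size,
        refset_size=config.refset_size,
        eval_budget=config.eval_budget,
        seed=config.seed,
    )
    result = _bao.scatter_search_bao(phantom, prescription, pool,
                                     config.n_beams, params, cache=cache)
    log.info("best configuration %s with F=%.6g after %d evaluations",
             result.best_configuration, result.best_objective, result.evaluations)
    _write_json({
        "seed": result.seed,
        "evaluations": result.evaluations,
        "best_trace": [[e, f] for e, f in result.trace],
        "solutions": [{"angles": list(c), "objective": f}
                      for c, f in result.solutions],
    }, out / "bao_result.json")

    log.info("stage 3/4: equispaced baseline")
    equi = equispaced_configuration(config.n_beams, config.equispaced_start_deg, pool)

    log.info("stage 4/4: plan evaluation")
    mtx_dir = out / "dose_matrices"
    mtx_dir.mkdir(exist_ok=True)
    summary = {"optimal": {"angles": list(result.best_configuration)},
               "equispaced": {"angles": list(equi)}}
    reports: dict[str, PlanIndices] = {}
    for label, cfg in (("optimal", result.best_configuration), ("equispaced", equi)):
        mats = cache.matrices.get_config(cfg)
        for m in mats:
            stem = f"angle_{m.gantry_angle_deg:g}"
            save_dose_matrix(m, mtx_dir / f"{stem}.mtx", mtx_dir / f"{stem}.json",
                             kernel)
        fmo_res = solve_fmo(mats, prescription, phantom, solver)
        dose = compute_dose(mats, fmo_res.fluence_maps)
        save_fluence(cfg, fmo_res.fluence_maps, [m.beamlets for m in mats],
                     out / f"fluence_{label}.csv")
        curves = [cumulative_dvh(dose, s, phantom=phantom) for s in phantom.structures]
        save_dvh(curves, out / f"dvh_{label}.csv")
        reports[label] = plan_report(dose, phantom, prescription)
        summary[label]["objective"] = fmo_res.objective
        summary[label]["indices"] = reports[label].to_dict()
    summary["difference_optimal_minus_equispaced"] = compare_plans(
        reports["optimal"], reports["equispaced"]
    )
    _write_json(summary, out / "report.json")
    return summary
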