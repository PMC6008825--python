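"""Plan evaluation: DVH curves, dose statistics, homogeneity and conformity.

The quality of a treatment plan is summarized with the standard indices:

* cumulative dose-volume histogram (DVH) — percent of a structure's volume
  receiving at least each dose level;
* D5 / D95 — the minimum dose within the hottest 5% / 95% of the volume
  (near-maximum and near-minimum doses), by the exact rank-order
  definition so worked examples are bit-stable;
* homogeneity index HI = (D5 - D95) / D_p * 100, ideal 0;
* Van't Riet conformity index CI = CI1 * CI2 with
  CI1 = V_t,ref / V_t and CI2 = V_t,ref / V_ref at the reference isodose
  (default 95% of the prescribed dose), ideal 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fmo import SQUARE_DEVIATION, Prescription
from .phantoms import Phantom, Structure


@dataclass(frozen=True)
class DVHCurve:
    structure: str
    dose_edges: np.ndarray = field(repr=False)  # ascending Gy grid from 0
    volume_fraction: np.ndarray = field(repr=False)  # percent receiving >= dose


def _structure_dose(dose: np.ndarray, structure, phantom: Phantom | None):
    """Dose values inside a structure; accepts row indices or a Structure."""
    dose = np.asarray(dose, dtype=float)
    if isinstance(structure, Structure) or isinstance(structure, str):
        if phantom is None:
            raise ValueError("phantom is required when passing a Structure")
        rows = phantom.body_rows(structure)
    else:
        rows = np.asarray(structure, dtype=np.int64)
    if rows.size == 0:
        raise ValueError("structure has no voxels")
    return dose[rows]


def cumulative_dvh(dose, structure, bin_width_gy: float = 0.1,
                   phantom: Phantom | None = None,
                   name: str = "") -> DVHCurve:
    """Cumulative DVH evaluated on a regular dose grid from 0 Gy.

    ``volume_fraction[k]`` is the percent of structure voxels with dose at
    least ``dose_edges[k]``; the grid extends one bin past the maximum dose
    so every curve ends at 0.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    d = _structure_dose(dose, structure, phantom)
    top = float(d.max()) if d.size else 0.0
    n_edges = int(math.ceil(top / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    frac = 100.0 * (d[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 100.0  # every voxel receives at least 0 Gy
    label = name or (structure if isinstance(structure, str)
                     else getattr(structure, "name", ""))
    return DVHCurve(structure=label, dose_edges=edges, volume_fraction=frac)


def dose_at_volume(dose, structure, volume_percent: float,
                   phantom: Phantom | None = None) -> float:
    """D_q: minimum dose within the hottest ``volume_percent`` of the structure.

    Rank-order definition: with doses sorted descending, D_q is the value at
    rank ceil(q/100 * n_voxels).
    """
    if not 0 < volume_percent < 100:
        raise ValueError("volume_percent must lie strictly between 0 and 100")
    d = np.sort(_structure_dose(dose, structure, phantom))[::-1]
    rank = math.ceil(volume_percent / 100.0 * d.size)
    return float(d[rank - 1])


def homogeneity_index(d5: float, d95: float, dp: float) -> float:
    """HI = (D5 - D95) / D_p * 100 (percent); 0 is ideal."""
    if dp <= 0:
        raise ValueError("prescribed dose must be positive")
    return (d5 - d95) / dp * 100.0


def conformity_index(dose, target, dp: float,
                     reference_fraction: float = 0.95,
                     phantom: Phantom | None = None) -> tuple[float, float, float]:
    """Van't Riet (CI, CI1, CI2) at the reference isodose.

    ``V_ref`` counts all body voxels with dose at least
    ``reference_fraction * dp``; ``V_t,ref`` those inside the target. With an
    empty reference isodose volume CI2 and CI are 0 by convention.
    """
    if not 0 < reference_fraction <= 1:
        raise ValueError("reference_fraction must lie in (0, 1]")
    dose = np.asarray(dose, dtype=float)
    d_t = _structure_dose(dose, target, phantom)
    level = reference_fraction * dp
    v_t = d_t.size
    v_t_ref = int((d_t >= level).sum())
    v_ref = int((dose >= level).sum())
    ci1 = v_t_ref / v_t
    if v_ref == 0:
        return 0.0, ci1, 0.0
    ci2 = v_t_ref / v_ref
    return ci1 * ci2, ci1, ci2


@dataclass
class PlanIndices:
    """Per-structure dose statistics plus per-target HI and CI."""

    per_structure: pd.DataFrame  # index: structure; mean, max, D5, D95 (Gy)
    per_target: pd.DataFrame  # index: target; Dp, HI (%), CI, CI1, CI2

    def to_dict(self) -> dict:
        return {
            "structures": self.per_structure.round(10).to_dict(orient="index"),
            "targets": self.per_target.round(10).to_dict(orient="index"),
        }


def plan_report(dose, phantom: Phantom, prescription: Prescription,
                reference_fraction: float = 0.95) -> PlanIndices:
    """Dose statistics for every structure and HI/CI for every target.

    HI and CI are computed per target against that target's own prescribed
    dose from the prescription.
    """
    dose = np.asarray(dose, dtype=float)
    rows = {}
    for s in phantom.structures:
        d = dose[phantom.body_rows(s)]
        rows[s.name] = {
            "mean_gy": float(d.mean()),
            "max_gy": float(d.max()),
            "D5_gy": dose_at_volume(dose, s, 5.0, phantom),
            "D95_gy": dose_at_volume(dose, s, 95.0, phantom),
        }
    targets = {}
    prescribed = {t.structure: t.dose_gy for t in prescription.terms
                  if t.kind == SQUARE_DEVIATION}
    for t in phantom.targets:
        if t.name not in prescribed:
            continue
        dp = prescribed[t.name]
        d5 = rows[t.name]["D5_gy"]
        d95 = rows[t.name]["D95_gy"]
        ci, ci1, ci2 = conformity_index(dose, t, dp, reference_fraction, phantom)
        targets[t.name] = {
            "Dp_gy": dp,
            "HI_pct": homogeneity_index(d5, d95, dp),
            "CI": ci,
            "CI1": ci1,
            "CI2": ci2,
        }
    return PlanIndices(
        per_structure=pd.DataFrame.from_dict(rows, orient="index"),
        per_target=pd.DataFrame.from_dict(targets, orient="index"),
    )


def compare_plans(plan_a: PlanIndices, plan_b: PlanIndices) -> dict:
    """Per-metric differences (plan A minus plan B) for shared structures."""
    ds = (plan_a.per_structure - plan_b.per_structure).dropna(how="all")
    dt = (plan_a.per_target - plan_b.per_target).dropna(how="all")
    return {
        "structures": ds.round(10).to_dict(orient="index"),
        "targets": dt.round(10).to_dict(orient="index"),
    }
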