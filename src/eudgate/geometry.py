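"""Geometric features of interfraction CTV deformation.

The directed Hausdorff distance HDD_i of a deformed CTV_i from the planning
CTV is defined as the radius of the minimal isotropic expansion of CTV_plan
that contains CTV_i — equivalently the maximum, over CTV_i voxels, of the
Euclidean distance to CTV_plan.  The achieving voxel is the Hausdorff point
HDP_i; HDP_worst is the HDP_i with the largest HDD_i over a patient's
fractions.

The dosimetric anchor point is PD_min_global: the argmin-dose voxel of the
coldest fraction, mapped back to planning geometry through the inverse
displacement.  Propagating it forward through every fraction's field gives
the per-fraction dose at that point (D_PDmin_global_i) and the scalar
projection of each fraction's deformation onto the worst fraction's
direction (Scalar_PDmin_global_i_x) — a surrogate for motion along the
steepest dose gradient.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .accumulation import invert_point
from .eud import DVH, GEUDParams, SFModelParams, compute_dvh, d_min, dose_percentile, eud_sf, geud
from .grids import DisplacementField, DoseGrid, StructureMask, _check_same_grid

__all__ = [
    "hausdorff_expansion",
    "hdp_worst",
    "pd_min_global",
    "propagate_point",
    "scalar_pdmin",
    "delta_l_hdp_worst",
    "deformation_variance_decomposition",
    "extract_features",
]


def distance_to_structure(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) of every voxel to the nearest mask voxel."""
    return distance_transform_edt(~mask.values, sampling=mask.grid.spacing)


def hausdorff_expansion(
    ctv_plan: StructureMask,
    ctv_i: StructureMask,
    _plan_distance: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Directed Hausdorff distance of CTV_i from CTV_plan and its point.

    Returns ``(HDD_i in mm, HDP_i world point)``.  HDD_i is zero iff
    CTV_i ⊆ CTV_plan.  Ties are broken by the lowest linear voxel index.
    ``_plan_distance`` lets series loops reuse the plan distance transform.
    """
    _check_same_grid(ctv_plan, ctv_i)
    if ctv_plan.n_voxels == 0 or ctv_i.n_voxels == 0:
        raise ValueError("both masks must be nonempty")
    dist = _plan_distance if _plan_distance is not None else distance_to_structure(ctv_plan)
    vals = np.where(ctv_i.values, dist, -np.inf)
    flat = int(np.argmax(vals))  # first occurrence = lowest linear index
    idx = np.unravel_index(flat, vals.shape)
    return float(dist[idx]), ctv_plan.grid.index_to_world(np.asarray(idx))


def hdp_worst(series_hdds: list[tuple[float, np.ndarray]]) -> tuple[int, np.ndarray]:
    """Fraction index and point of the largest HDD_i; ties → earliest."""
    if not series_hdds:
        raise ValueError("need at least one fraction")
    hdds = np.asarray([h for h, _ in series_hdds])
    i = int(np.argmax(hdds))
    return i, np.asarray(series_hdds[i][1])


def pd_min_global(
    dmins: list[float],
    argmin_points_world: list[np.ndarray],
    fields: list[DisplacementField],
) -> tuple[int, np.ndarray]:
    """Coldest fraction x and its argmin point mapped back to planning.

    ``dmins[i]`` and ``argmin_points_world[i]`` are the per-fraction minimum
    CTV_i dose and its voxel center; the winning point is pulled back
    through fraction x's displacement field by fixed-point inversion.
    Ties go to the earliest fraction.
    """
    if not (len(dmins) == len(argmin_points_world) == len(fields)) or not dmins:
        raise ValueError("need matching nonempty per-fraction inputs")
    x = int(np.argmin(dmins))
    p_frac = np.asarray(argmin_points_world[x], dtype=float)
    q_plan = invert_point(fields[x], p_frac)
    return x, q_plan


def propagate_point(
    p_plan: np.ndarray, field_i: DisplacementField, dose: DoseGrid
) -> tuple[np.ndarray, float]:
    """Push a planning point through a fraction's field and sample the dose.

    Returns the displaced point ``p + u_i(p)`` and the trilinearly
    interpolated dose there (clamped to the grid boundary).
    """
    p = np.asarray(p_plan, dtype=float)
    moved = p + field_i.sample(p)[0]
    return moved, float(dose.sample(moved)[0])


def scalar_pdmin(
    p_plan: np.ndarray, field_i: DisplacementField, field_x: DisplacementField
) -> float:
    """Signed projection (mm) of fraction i's deformation at the global
    minimum-dose point onto the worst fraction's deformation direction."""
    p = np.asarray(p_plan, dtype=float)
    v_i = field_i.sample(p)[0]
    v_x = field_x.sample(p)[0]
    n = np.linalg.norm(v_x)
    if n == 0:
        warnings.warn("degenerate reference direction |v_x| = 0; returning 0")
        return 0.0
    return float(v_i @ (v_x / n))


def delta_l_hdp_worst(hdp_worst_plan: np.ndarray, field_i: DisplacementField) -> float:
    """Length (mm) of fraction i's deformation vector at the HDP_worst
    location in planning geometry."""
    return float(np.linalg.norm(field_i.sample(np.asarray(hdp_worst_plan, float))[0]))


def deformation_variance_decomposition(samples) -> tuple[np.ndarray, np.ndarray]:
    """Split per-patient deformation samples into systematic and random SDs.

    ``samples`` is a sequence over patients of ``(n_fractions, 3)`` arrays
    (deformation vectors at a point, or differences of vectors between two
    points as in the clinical analysis).  Per axis, the random SD is the
    pooled within-patient SD and the systematic SD is the SD over patients
    of the per-patient means.
    """
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in samples]
    if len(arrays) < 2:
        raise ValueError("need at least two patients")
    if any(a.shape[0] < 2 for a in arrays):
        raise ValueError("random SD undefined: every patient needs >= 2 fractions")
    means = np.stack([a.mean(axis=0) for a in arrays])
    systematic = means.std(axis=0, ddof=1)
    ss = sum(((a - a.mean(axis=0)) ** 2).sum(axis=0) for a in arrays)
    dof = sum(a.shape[0] - 1 for a in arrays)
    random = np.sqrt(ss / dof)
    return systematic, random


def extract_features(
    series,
    geud_params: GEUDParams = GEUDParams(),
    sf_params: SFModelParams | None = None,
) -> pd.DataFrame:
    """Per-fraction feature table for one patient series.

    One row per fraction with the normalized effectiveness measures
    (gEUD_i, EUD_SF_i), the normalized minimum CTV_i dose and high-dose DVH
    percentiles, and the geometric deformation features (HDD_i, ΔL at
    HDP_worst, dose and scalar projection at the propagated global
    minimum-dose point).  Doses follow the static-dose-cloud approximation:
    the planning dose is evaluated on the deformed CTV_i voxels.
    """
    sf = sf_params or SFModelParams(n_fractions=series.n_plan_fractions)
    rx = series.prescription
    per_fraction_scale = 1.0 / series.n_plan_fractions
    plan_dist = distance_to_structure(series.ctv_plan)

    rows = []
    hdds, dmins, argmins = [], [], []
    for fld, ctv_i in series.fractions:
        dvh = compute_dvh(series.plan_dose, ctv_i)
        g = geud(dvh, geud_params, prescription=rx)
        dvh_frac = DVH(dvh.bin_edges * per_fraction_scale, dvh.cum_volume)
        esf = eud_sf(dvh_frac, sf, prescription=rx)
        dm, idx = d_min(series.plan_dose, ctv_i)
        hdd, hdp = hausdorff_expansion(series.ctv_plan, ctv_i, _plan_distance=plan_dist)
        rows.append(
            {
                "D_min": dm / rx,
                "gEUD": g,
                "EUD_SF": esf,
                "HDD_mm": hdd,
                "D99_9": dose_percentile(dvh, 99.9) / rx,
                "D99": dose_percentile(dvh, 99) / rx,
                "D98": dose_percentile(dvh, 98) / rx,
                "D50": dose_percentile(dvh, 50) / rx,
            }
        )
        hdds.append((hdd, hdp))
        dmins.append(dm)
        argmins.append(series.grid.index_to_world(np.asarray(idx)))

    fields = [fld for fld, _ in series.fractions]
    worst_idx, hdp_w = hdp_worst(hdds)
    # map HDP_worst (a CTV_i voxel in the fraction's geometry) back to planning
    hdp_w_plan = invert_point(fields[worst_idx], hdp_w)
    x, q_plan = pd_min_global(dmins, argmins, fields)
    for i, row in enumerate(rows):
        _, d_at = propagate_point(q_plan, fields[i], series.plan_dose)
        row["D_PDmin_global"] = d_at / rx
        row["Scalar_PDmin_mm"] = scalar_pdmin(q_plan, fields[i], fields[x])
        row["dL_HDPworst_mm"] = delta_l_hdp_worst(hdp_w_plan, fields[i])
        row["patient_id"] = series.patient_id
        row["fraction"] = i + 1

    df = pd.DataFrame(rows)
    cols = [
        "patient_id", "fraction", "D_min", "gEUD", "EUD_SF", "HDD_mm",
        "dL_HDPworst_mm", "D_PDmin_global", "Scalar_PDmin_mm",
        "D99_9", "D99", "D98", "D50",
    ]
    return df[cols]
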