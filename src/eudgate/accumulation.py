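"""Deformable dose accumulation under the static-dose-cloud approximation.

The planned dose distribution is treated as fixed in space while the anatomy
deforms through it: a tissue element at planning point ``q`` receives, at
fraction ``i``, the planned dose at its displaced position ``q + u_i(q)``.
Summing these pulled-back per-fraction doses on the planning grid yields the
accumulated distribution, on which gEUD_acc and the accumulated minimum dose
are evaluated for CTV_plan.

Displacement-field inversion (needed to warp structures from planning to
fraction geometry and to map points back) uses per-voxel fixed-point
iteration.  A gamma-index comparison (dose difference / distance to
agreement) is provided to check the static-dose-cloud assumption.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .eud import compute_dvh, d_min, geud, GEUDParams
from .grids import DisplacementField, DoseGrid, GridSpec, StructureMask, _check_same_grid

__all__ = [
    "GammaCriteria",
    "invert_field",
    "composition_residual_rms",
    "pullback_dose",
    "warp_mask",
    "invert_point",
    "accumulate",
    "gamma_pass_rate",
]


def _index_mesh(spec: GridSpec) -> np.ndarray:
    """(3, nz, ny, nx) array of voxel indices."""
    return np.indices(spec.shape).astype(float)


def _sample_field_at_index(field: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear sample of a (…, 3) field at fractional indices (3, ...)."""
    out = np.empty(idx.shape[1:] + (3,))
    for c in range(3):
        out[..., c] = map_coordinates(field[..., c], idx, order=1, mode="nearest")
    return out


def invert_field(
    field: DisplacementField,
    tol_mm: float = 0.01,
    max_iter: int = 50,
    max_residual_rms_mm: float = 0.1,
    roi: StructureMask | None = None,
) -> DisplacementField:
    """Invert a displacement field by per-voxel fixed-point iteration.

    Solves ``v(p) = -u(p + v(p))`` so that ``p + v(p)`` maps a fraction-
    geometry point back to planning geometry.  Converges for fields whose
    spatial Lipschitz constant is below 1 (guaranteed when the warp Jacobian
    stays positive).

    The residual contract is evaluated over ``roi`` when given (e.g. the
    dilated target region a caller actually resamples), otherwise over all
    voxels whose back-mapped point stays inside the grid.

    Raises
    ------
    RuntimeError
        If the composition residual RMS still exceeds
        ``max_residual_rms_mm`` after ``max_iter`` sweeps; the message lists
        the worst voxels.
    """
    spec = field.grid
    spacing = np.asarray(spec.spacing)
    u = field.values
    base = _index_mesh(spec)
    v = np.zeros_like(u)
    for _ in range(max_iter):
        idx = base + np.moveaxis(v / spacing, -1, 0)
        v_new = -_sample_field_at_index(u, idx)
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol_mm:
            break
    inv = DisplacementField(spec, v)
    res = _composition_residual(field, inv)
    # the inverse is only defined where the pre-image stays inside the grid;
    # boundary voxels whose back-mapped point is clamped are excluded
    idx = _index_mesh(spec) + np.moveaxis(v / spacing, -1, 0)
    inside = np.ones(spec.shape, dtype=bool)
    for c, n in enumerate(spec.shape):
        inside &= (idx[c] >= 0) & (idx[c] <= n - 1)
    if roi is not None:
        inside &= roi.values
    mag2 = (res**2).sum(axis=-1)
    rms = float(np.sqrt(mag2[inside].mean())) if inside.any() else 0.0
    if rms > max_residual_rms_mm:
        mag = np.where(inside, np.sqrt(mag2), -np.inf)
        worst = np.argsort(mag.ravel())[-3:][::-1]
        worst_vox = [tuple(int(i) for i in np.unravel_index(w, spec.shape)) for w in worst]
        raise RuntimeError(
            f"field inversion residual RMS {rms:.3g} mm exceeds "
            f"{max_residual_rms_mm} mm; worst voxels {worst_vox}"
        )
    return inv


def _composition_residual(field: DisplacementField, inverse: DisplacementField) -> np.ndarray:
    """Residual r(p) = v(p) + u(p + v(p)); zero for a perfect inverse."""
    spec = field.grid
    spacing = np.asarray(spec.spacing)
    idx = _index_mesh(spec) + np.moveaxis(inverse.values / spacing, -1, 0)
    return inverse.values + _sample_field_at_index(field.values, idx)


def composition_residual_rms(
    field: DisplacementField, inverse: DisplacementField, roi: StructureMask | None = None
) -> float:
    """RMS deviation (mm) of field∘inverse from the identity, over an ROI."""
    res = _composition_residual(field, inverse)
    mag2 = (res**2).sum(axis=-1)
    if roi is not None:
        mag2 = mag2[roi.values]
    return float(np.sqrt(mag2.mean()))


def pullback_dose(dose: DoseGrid, field: DisplacementField) -> DoseGrid:
    """Resample a dose through a displacement field.

    The output at planning voxel ``p`` is the trilinear sample of ``dose``
    at ``p + field(p)``; samples outside the grid take the boundary value.
    """
    _check_same_grid(dose, field)
    spec = dose.grid
    spacing = np.asarray(spec.spacing)
    idx = _index_mesh(spec) + np.moveaxis(field.values / spacing, -1, 0)
    out = map_coordinates(dose.values, idx, order=1, mode="nearest")
    return DoseGrid(spec, out)


def warp_mask(mask: StructureMask, inverse_field: DisplacementField) -> StructureMask:
    """Warp a planning structure to fraction geometry (nearest neighbour).

    A fraction-geometry voxel ``p`` belongs to the warped structure iff its
    pre-image ``p + inverse_field(p)`` lies in the planning mask.
    """
    _check_same_grid(mask, inverse_field)
    spec = mask.grid
    spacing = np.asarray(spec.spacing)
    idx = _index_mesh(spec) + np.moveaxis(inverse_field.values / spacing, -1, 0)
    vals = map_coordinates(mask.values.astype(np.uint8), idx, order=0, mode="constant")
    return StructureMask(spec, vals.astype(bool))


def invert_points(
    field: DisplacementField,
    targets_mm: np.ndarray,
    tol_mm: float = 0.01,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pre-image search: find q with q + u(q) = target per row.

    Returns ``(points, residual_mm)``; non-contractive spots may leave a
    residual above tolerance, which the caller can inspect.
    """
    targets = np.atleast_2d(np.asarray(targets_mm, dtype=float))
    q = targets.copy()
    active = np.arange(len(targets))
    for _ in range(max_iter):
        q_new = targets[active] - field.sample(q[active])
        moved = np.abs(q_new - q[active]).max(axis=1)
        q[active] = q_new
        active = active[moved >= tol_mm]
        if active.size == 0:
            break
    residual = np.sqrt(((q + field.sample(q) - targets) ** 2).sum(axis=1))
    return q, residual


def warp_mask_band(
    mask: StructureMask, field: DisplacementField, band_extra_mm: float = 2.0
) -> StructureMask:
    """Warp a planning mask to fraction geometry by pointwise inversion.

    Only voxels within ``max |u| + band_extra_mm`` of the mask surface can
    change membership; their pre-images are found with ``invert_points``
    and sampled nearest-neighbour.  Equivalent to warping through the full
    inverse field, at a fraction of the cost.
    """
    _check_same_grid(mask, field)
    spec = mask.grid
    from scipy.ndimage import distance_transform_edt

    reach = field.max_magnitude() + band_extra_mm
    if reach <= band_extra_mm:  # zero field
        return StructureMask(spec, mask.values.copy())
    d_out = distance_transform_edt(~mask.values, sampling=spec.spacing)
    d_in = distance_transform_edt(mask.values, sampling=spec.spacing)
    band = (d_out <= reach) & (d_in <= reach)
    pts_idx = np.argwhere(band)
    targets = spec.index_to_world(pts_idx)
    pre, _ = invert_points(field, targets)
    src_idx = np.round(spec.world_to_index(pre)).astype(int)
    for c, n in enumerate(spec.shape):
        np.clip(src_idx[:, c], 0, n - 1, out=src_idx[:, c])
    out = mask.values.copy()
    out[tuple(pts_idx.T)] = mask.values[tuple(src_idx.T)]
    return StructureMask(spec, out)


def invert_point(
    field: DisplacementField,
    target_mm: np.ndarray,
    tol_mm: float = 0.01,
    max_iter: int = 50,
) -> np.ndarray:
    """Find the planning point ``q`` with ``q + u(q) = target`` (fixed point).

    Raises RuntimeError if the iteration does not converge.
    """
    target = np.asarray(target_mm, dtype=float)
    q = target.copy()
    for _ in range(max_iter):
        q_new = target - field.sample(q)[0]
        if np.abs(q_new - q).max() < tol_mm:
            return q_new
        q = q_new
    raise RuntimeError(
        f"point inversion did not converge for target {target} "
        f"(last iterate {q}); field may not be invertible there"
    )


def accumulate(series, geud_params: GEUDParams = GEUDParams()):
    """Accumulate the per-fraction delivered dose on the planning anatomy.

    Each generated fraction delivers the planned distribution scaled to one
    fraction; the accumulated course dose at planning voxel ``q`` is the
    mean over fractions of the plan dose sampled at ``q + u_i(q)``, times
    the planned total (uniform fractionation, so the result is on the same
    scale as the plan and directly comparable to the prescription).

    Returns
    -------
    (DoseGrid, float, float)
        Accumulated dose, normalized gEUD_acc and normalized accumulated
        D_min, both evaluated on CTV_plan and divided by the prescription.
    """
    if len(series.fractions) == 0:
        raise ValueError("cannot accumulate an empty fraction series")
    total = np.zeros(series.grid.shape)
    for fld, _ in series.fractions:
        total += pullback_dose(series.plan_dose, fld).values
    acc = DoseGrid(series.grid, total / len(series.fractions))
    dvh = compute_dvh(acc, series.ctv_plan)
    geud_acc = geud(dvh, geud_params, prescription=series.prescription)
    dmin_acc = d_min(acc, series.ctv_plan)[0] / series.prescription
    return acc, geud_acc, dmin_acc


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-index acceptance criteria.

    dta in mm; dd as a fraction of the normalization dose (0.03 = 3%);
    voxels with reference dose below ``dose_threshold`` × normalization are
    excluded from scoring.
    """

    dta: float = 3.0
    dd: float = 0.03
    dose_threshold: float = 0.1
    norm: float | None = None  # defaults to the reference maximum (global)

    def __post_init__(self) -> None:
        if self.dta <= 0 or self.dd <= 0:
            raise ValueError("dta and dd must be positive")


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    crit: GammaCriteria,
    roi: StructureMask,
) -> np.ndarray:
    """Gamma index per scored ROI voxel (NaN elsewhere).

    Exhaustive search on the voxel lattice within a radius of 3×DTA —
    sufficient because any farther match already has a distance term ≥ 3.
    Global normalization (single reference dose) is used.
    """
    _check_same_grid(reference, evaluated)
    _check_same_grid(reference, roi)
    spec = reference.grid
    norm = crit.norm if crit.norm is not None else float(reference.values.max())
    scored = roi.values & (reference.values >= crit.dose_threshold * norm)
    if not scored.any():
        raise ValueError("no ROI voxel above the dose threshold to score")
    spacing = np.asarray(spec.spacing)
    radius = 3.0 * crit.dta
    reach = np.floor(radius / spacing).astype(int)
    ref = reference.values
    ev = evaluated.values
    shape = spec.shape
    best = np.full(shape, np.inf)
    offsets = sorted(
        itertools.product(*(range(-r, r + 1) for r in reach)),
        key=lambda o: (o[0] * spacing[0]) ** 2 + (o[1] * spacing[1]) ** 2 + (o[2] * spacing[2]) ** 2,
    )
    for off in offsets:
        dist2 = sum((o * s) ** 2 for o, s in zip(off, spacing))
        if dist2 > radius**2:
            continue
        space_term = dist2 / crit.dta**2
        cur_max = best[scored].max()
        if space_term >= cur_max:
            break  # farther offsets cannot lower any scored voxel's minimum
        # overlapping slices of the evaluated dose shifted by -off
        src = tuple(
            slice(max(0, -o), min(n, n - o)) for o, n in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(n, n + o)) for o, n in zip(off, shape)
        )
        g2 = np.full(shape, np.inf)
        g2[dst] = ((ev[src] - ref[dst]) / (crit.dd * norm)) ** 2 + space_term
        np.minimum(best, g2, out=best)
    gamma = np.sqrt(best)
    gamma[~scored] = np.nan
    return gamma


def gamma_pass_rate(
    reference: DoseGrid,
    evaluated: DoseGrid,
    crit: GammaCriteria,
    roi: StructureMask,
) -> float:
    """Fraction of scored ROI voxels with gamma ≤ 1."""
    g = gamma_map(reference, evaluated, crit, roi)
    scored = np.isfinite(g)
    return float((g[scored] <= 1.0).mean())
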