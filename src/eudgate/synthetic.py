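"""Synthetic exhale-gated lung radiotherapy cohorts.

Generates seeded patients — a planning CTV, a planning dose with a
prescription-level plateau and anisotropic penumbra, and per-fraction
residual deformation fields with deformed CTVs — with the statistical
structure of a 10-patient, 218-fraction clinical series: CTV volumes of
149–344 cm³, 11–40 image-guided fractions per patient, cranio-caudal dose
gradients of ~5–12.5 %/mm versus ~1.5–6.25 %/mm axially, interfraction
deformations with per-patient systematic and per-fraction random
components, and a small minority of fractions with a large localized
excursion of the CTV surface that produces a per-fraction gEUD drop.

Deformation scale convention: the clinically reported systematic
(1.7/3.0/2.3 mm in x/y/z) and random (3.0/3.3/3.9 mm) SDs describe
*differences of deformation vectors between two points* of the CTV.
``CohortConfig.systematic_sd``/``random_sd`` use that same scale (in the
package's (z, y, x) axis order); the per-point Gaussian random fields are
scaled by 1/sqrt(2) so that differences between decorrelated points
reproduce the configured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .accumulation import warp_mask_band
from .grids import DisplacementField, DoseGrid, GridSpec, StructureMask

__all__ = [
    "CohortConfig",
    "PatientSeries",
    "TABLE_CTV_VOLUMES_CM3",
    "TABLE_FRACTION_COUNTS",
    "generate_ctv",
    "generate_plan_dose",
    "generate_fraction_field",
    "generate_cohort",
    "generate_feature_table",
]

# Empirical per-patient CTV volumes (cm³) and examined-fraction counts of the
# emulated 10-patient clinical series (218 fractions in total).
TABLE_CTV_VOLUMES_CM3 = (149.8, 176.1, 151.5, 321.0, 344.2, 177.8, 170.0, 228.2, 231.5, 149.3)
TABLE_FRACTION_COUNTS = (28, 25, 33, 11, 12, 40, 30, 13, 14, 12)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    All 3-vectors are in (z, y, x) axis order with z cranio-caudal.
    Deformation SDs are on the two-point-difference scale (see module
    docstring).  Gradients are %/mm of prescription.
    """

    n_patients: int = 10
    fractions_range: tuple[int, int] = (11, 40)
    ctv_volume_range: tuple[float, float] = (149.3, 344.2)
    prescription_dose: float = 60.0
    n_plan_fractions: int = 30
    ptv_margin: float = 5.0
    gradient_cc: tuple[float, float] = (5.0, 12.5)
    gradient_axial: tuple[float, float] = (1.5, 6.25)
    systematic_sd: tuple[float, float, float] = (2.3, 3.0, 1.7)
    random_sd: tuple[float, float, float] = (3.9, 3.3, 3.0)
    correlation_length_mm: float = 15.0
    edge_taper_mm: float = 16.0
    large_excursion_prob: float = 0.05
    excursion_amplitude: tuple[float, float] = (8.0, 12.0)
    excursion_sigma_mm: float = 12.0
    boost_rate: float = 0.5  # %/mm dose increase inward of the PTV surface
    boost_cap: float = 1.05  # plateau ceiling, fraction of prescription
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    use_table_values: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fractions_range[0] > self.fractions_range[1]:
            raise ValueError("fractions_range must be a nonempty range")
        if self.ctv_volume_range[0] > self.ctv_volume_range[1]:
            raise ValueError("ctv_volume_range must be nonempty")
        if not (0 <= self.large_excursion_prob <= 1):
            raise ValueError("large_excursion_prob must lie in [0, 1]")
        if any(s < 0 for s in self.systematic_sd + self.random_sd):
            raise ValueError("deformation SDs must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape, self.grid_spacing)


@dataclass
class PatientSeries:
    """One synthetic patient: plan geometry plus per-fraction deformations."""

    patient_id: str
    grid: GridSpec
    ctv_plan: StructureMask
    plan_dose: DoseGrid
    prescription: float
    fractions: list[tuple[DisplacementField, StructureMask]] = field(default_factory=list)
    n_plan_fractions: int = 30

    def __post_init__(self) -> None:
        if self.ctv_plan.n_voxels == 0:
            raise ValueError("ctv_plan must be nonempty")


def _ellipsoid_field(spec: GridSpec, centers, semi_axes) -> np.ndarray:
    """min over ellipsoids of the normalized quadratic form (<=1 inside)."""
    coords = [
        np.arange(n) * s + o
        for n, s, o in zip(spec.shape, spec.spacing, spec.origin)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    best = np.full(spec.shape, np.inf)
    for c, ax in zip(centers, semi_axes):
        q = ((zz - c[0]) / ax[0]) ** 2 + ((yy - c[1]) / ax[1]) ** 2 + ((xx - c[2]) / ax[2]) ** 2
        np.minimum(best, q, out=best)
    return best


def generate_ctv(
    spec: GridSpec, volume_target_cm3: float, seed: int | np.random.Generator = 0
) -> StructureMask:
    """Smooth connected blob (union of perturbed ellipsoids) matching a
    target volume within 5% (achieved by bisection on a global scale).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    if volume_target_cm3 * 1000.0 > 0.9 * extent.prod():
        raise ValueError(
            f"target volume {volume_target_cm3} cm³ exceeds grid capacity "
            f"({extent.prod() / 1000.0:.0f} cm³)"
        )
    center = np.asarray(spec.origin) + extent / 2
    # one main ellipsoid plus satellites overlapping it, mildly anisotropic
    n_lobes = 3
    centers = [center]
    semi = [rng.uniform(0.8, 1.2, 3)]
    for _ in range(n_lobes - 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        centers.append(center + direction * rng.uniform(0.3, 0.6) * semi[0].mean())
        semi.append(rng.uniform(0.5, 0.9, 3))
    q = _ellipsoid_field(spec, centers, semi)  # scale-free shape function

    vox = spec.voxel_volume_mm3
    target_vox = volume_target_cm3 * 1000.0 / vox

    def count(scale: float) -> int:
        return int((q <= scale**2).sum())

    lo, hi = 1.0, 1.0
    while count(hi) < target_vox:
        hi *= 1.3
        if hi > extent.max():
            raise ValueError("target volume not achievable on this grid")
    while count(lo) > target_vox and lo > 1e-3:
        lo /= 1.3
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    mask = q <= hi**2
    got = mask.sum() * vox / 1000.0
    if abs(got - volume_target_cm3) / volume_target_cm3 > 0.05:
        raise ValueError(
            f"could not match target volume within 5% ({got:.1f} vs {volume_target_cm3} cm³)"
        )
    return StructureMask(spec, mask)


def generate_plan_dose(
    ctv: StructureMask,
    margin_mm: float,
    prescription: float,
    gradients: tuple[float, float],
    boost_rate: float = 0.5,
    boost_cap: float = 1.05,
) -> DoseGrid:
    """Planning dose: prescription plateau on CTV + margin, anisotropic falloff.

    Outside the PTV (= CTV dilated by ``margin_mm``) the dose falls linearly
    with an effective distance that costs ``gradients[0]`` %/mm along the
    cranio-caudal (z) axis and ``gradients[1]`` %/mm axially.  Inside the
    PTV the dose rises mildly with depth (``boost_rate`` %/mm, capped at
    ``boost_cap`` × prescription), emulating the slight target overdose of
    clinical plans, so the plateau satisfies dose ≥ prescription.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    g_cc, g_ax = gradients
    spec = ctv.grid
    sp = np.asarray(spec.spacing)
    # PTV: CTV dilated by the margin (Euclidean, mm)
    dist_to_ctv = distance_transform_edt(~ctv.values, sampling=sp)
    ptv = dist_to_ctv <= margin_mm
    if g_cc == 0 and g_ax == 0:
        outside = np.zeros(spec.shape)
    else:
        # effective %-distance of outside voxels to the PTV surface:
        # z costs g_cc %/mm, x/y cost g_ax %/mm
        outside = distance_transform_edt(
            ~ptv, sampling=(sp[0] * g_cc, sp[1] * g_ax, sp[2] * g_ax)
        )
    depth = distance_transform_edt(ptv, sampling=sp)  # depth inside the PTV
    rel = np.where(
        ptv,
        np.minimum(1.0 + boost_rate * depth / 100.0, boost_cap),
        np.maximum(1.0 - outside / 100.0, 0.0),
    )
    return DoseGrid(spec, rel * prescription)


def _gaussian_random_field(
    spec: GridSpec, sd_point: np.ndarray, correlation_length_mm: float, rng
) -> np.ndarray:
    """Stationary Gaussian random field with exact per-axis point SD.

    White noise is smoothed periodically with a Gaussian kernel of the
    stated correlation length and rescaled by the kernel's theoretical L2
    norm, so the marginal SD at every voxel equals ``sd_point`` exactly in
    expectation (an empirical per-realization rescale would be biased by
    boundary effects and induce spurious cross-point correlation).
    """
    sigma_vox = correlation_length_mm / np.asarray(spec.spacing)
    norm = 1.0
    for n, s in zip(spec.shape, sigma_vox):
        i = np.arange(n, dtype=float)
        i = np.minimum(i, n - i)  # circular distance, matching mode="wrap"
        g = np.exp(-0.5 * (i / s) ** 2)
        g /= g.sum()
        norm *= np.sqrt((g**2).sum())
    out = np.zeros(spec.shape + (3,))
    for c in range(3):
        if sd_point[c] == 0:
            continue
        noise = rng.standard_normal(spec.shape)
        out[..., c] = gaussian_filter(noise, sigma=sigma_vox, mode="wrap") * (
            sd_point[c] / norm
        )
    return out


def _warp_jacobian_positive(field: np.ndarray, spacing) -> bool:
    """Check det(I + ∇u) > 0 at every voxel (finite differences)."""
    grads = np.empty(field.shape[:3] + (3, 3))
    for c in range(3):
        gz, gy, gx = np.gradient(field[..., c], *spacing)
        grads[..., c, 0] = gz
        grads[..., c, 1] = gy
        grads[..., c, 2] = gx
    jac = grads + np.eye(3)
    return bool((np.linalg.det(jac) > 0).all())


def _soft_cap_magnitude(u: np.ndarray, r0: float, rmax: float) -> np.ndarray:
    """Leave |u| <= r0 untouched, smoothly saturate larger magnitudes at rmax.

    Keeps the configured displacement statistics intact (only extreme tails
    are compressed) while bounding the worst-case displacement, which keeps
    the warp diffeomorphic once the boundary taper is applied.
    """
    mag = np.sqrt((u**2).sum(axis=-1, keepdims=True))
    capped = np.where(
        mag > r0, r0 + (rmax - r0) * np.tanh((mag - r0) / (rmax - r0)), mag
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > 0, capped / mag, 1.0)
    return u * scale


def _edge_taper_window(spec: GridSpec, taper_mm: float) -> np.ndarray:
    """Separable cosine window: 1 in the interior, 0 at the grid boundary."""
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        pos = np.arange(n) * s
        edge_dist = np.minimum(pos, pos[-1] - pos)
        t = np.clip(edge_dist / taper_mm, 0.0, 1.0)
        axes.append(0.5 * (1.0 - np.cos(np.pi * t)))
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def generate_fraction_field(
    spec: GridSpec,
    systematic=(0.0, 0.0, 0.0),
    random_sd=(0.0, 0.0, 0.0),
    correlation_length_mm: float = 15.0,
    excursion: dict | None = None,
    edge_taper_mm: float = 0.0,
    displacement_cap_mm: tuple[float, float] | None = (6.0, 9.0),
    seed: int | np.random.Generator = 0,
) -> DisplacementField:
    """One fraction's smooth residual deformation field.

    ``systematic`` is either a constant 3-vector (translation, mm) or a full
    ``(nz, ny, nx, 3)`` per-patient systematic field.  The random component
    is a Gaussian random field with per-axis *point* SD ``random_sd`` and
    spatial correlation ``correlation_length_mm``.  ``excursion``, if given,
    adds a localized Gaussian displacement bump
    ``{"center": mm-point, "direction": unit 3-vector, "amplitude": mm,
    "sigma": mm}``.  With ``edge_taper_mm > 0`` the whole field is rolled
    off smoothly to zero over that distance from the grid boundary
    (residual deformations are local to the target region; the far anatomy
    is fixed by the setup), which also keeps the warp well defined at the
    grid edge.  The warp is checked for invertibility (positive Jacobian);
    a failing excursion amplitude is damped with a warning.
    """
    if correlation_length_mm <= 0:
        raise ValueError("correlation_length_mm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    systematic = np.asarray(systematic, dtype=float)
    u = np.zeros(spec.shape + (3,))
    if systematic.ndim == 1:
        u += systematic
    else:
        u += systematic
    u += _gaussian_random_field(spec, np.asarray(random_sd, float), correlation_length_mm, rng)
    if displacement_cap_mm is not None:
        u = _soft_cap_magnitude(u, *displacement_cap_mm)
    window = (
        _edge_taper_window(spec, edge_taper_mm)[..., None]
        if edge_taper_mm > 0
        else None
    )

    def windowed(arr: np.ndarray) -> np.ndarray:
        return arr * window if window is not None else arr

    if excursion is not None:
        coords = [
            np.arange(n) * s + o
            for n, s, o in zip(spec.shape, spec.spacing, spec.origin)
        ]
        zz, yy, xx = np.meshgrid(*coords, indexing="ij")
        c = np.asarray(excursion["center"], float)
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        bump_shape = np.exp(-r2 / (2.0 * excursion["sigma"] ** 2))
        direction = np.asarray(excursion["direction"], float)
        direction = direction / np.linalg.norm(direction)
        amplitude = float(excursion["amplitude"])
        out = None
        base = windowed(u)
        # the bump models an anatomical baseline shift at the target itself
        # and is deliberately not rolled off toward the grid boundary
        for attempt in range(6):
            cand = base + bump_shape[..., None] * (amplitude * direction)
            if _warp_jacobian_positive(cand, spec.spacing):
                out = cand
                break
            warnings.warn(
                f"excursion bump of {amplitude:.1f} mm makes the warp "
                "non-invertible; damping amplitude"
            )
            amplitude *= 0.7
        if out is not None:
            return DisplacementField(spec, out)
        u = base  # fall through: bump abandoned, validate the baseline
    else:
        u = windowed(u)
    for _ in range(4):
        if _warp_jacobian_positive(u, spec.spacing):
            break
        # systematic+random alone should be diffeomorphic; rescale if not
        warnings.warn("random field non-invertible; damping by 0.7")
        u *= 0.7
    return DisplacementField(spec, u)


def generate_feature_table(
    n_patients: int = 10,
    fractions_range: tuple[int, int] = (11, 40),
    noise_sd: float = 0.01,
    deep_prob: float = 0.15,
    seed: int = 0,
):
    """Synthetic per-fraction feature table with a known ground truth.

    The normalized gEUD is a noisy monotone function of the normalized
    minimum CTV dose — flat near the prescription plateau, steeply falling
    once D_min drops below ~75% — with geometric features that carry only
    partial, noisy information: the scalar deformation projection and the
    dose at the propagated global minimum point correlate with D_min, while
    the Hausdorff distance and the deformation length at the worst Hausdorff
    point are dominated by deformation components irrelevant to the dose.
    Patients differ systematically in their D_min distributions.

    Used for validating the cross-validated regressors: a good model should
    recover the D_min → gEUD relation on held-out patients and rank D_min
    as the most important input.  ``deep_prob`` controls how many fractions
    sample the steep low-dose limb; the default deliberately over-samples it
    relative to the clinical rate so that the relation is identifiable on
    every held-out patient (this is a validation cohort, not an
    epidemiological one).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if len(TABLE_FRACTION_COUNTS) >= n_patients:
        counts = rng.permutation(
            [c for c in TABLE_FRACTION_COUNTS
             if fractions_range[0] <= c <= fractions_range[1]] or [fractions_range[0]]
        )
        counts = (
            counts[:n_patients]
            if len(counts) >= n_patients
            else rng.integers(fractions_range[0], fractions_range[1] + 1, n_patients)
        )
    else:
        counts = rng.integers(fractions_range[0], fractions_range[1] + 1, n_patients)

    def geud_of_dmin(d):
        return 1.03 - 1.2 * np.clip(0.75 - d, 0.0, None) ** 1.5

    rows = []
    for p in range(n_patients):
        # interpatient heterogeneity: per-patient location/spread of D_min
        loc = rng.uniform(0.88, 1.0)
        scale = rng.uniform(0.03, 0.08)
        n = int(counts[p])
        dmin = loc - np.abs(rng.normal(0.0, scale, n)) - rng.exponential(0.02, n)
        deep = rng.uniform(size=n) < deep_prob
        dmin = np.where(deep, rng.uniform(0.3, 0.7, n), dmin)
        geud = geud_of_dmin(dmin) + rng.normal(0.0, noise_sd, n)
        scalar = 14.0 * np.clip(1.0 - dmin, 0, None) + rng.normal(0, 2.0, n)
        d_pdmin = np.clip(dmin + rng.normal(0, 0.08, n), 0.0, 1.1)
        hdd = np.abs(rng.normal(5.0, 2.0, n)) + 2.0 * deep
        dl = np.abs(rng.normal(4.0, 1.8, n))
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"P{p:02d}", "fraction": i + 1,
                    "D_min": dmin[i], "gEUD": geud[i],
                    "EUD_SF": geud[i] + rng.normal(0, 0.005),
                    "HDD_mm": hdd[i], "dL_HDPworst_mm": dl[i],
                    "D_PDmin_global": d_pdmin[i], "Scalar_PDmin_mm": scalar[i],
                }
            )
    return pd.DataFrame(rows)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return np.argwhere(mask & ~binary_erosion(mask))


def generate_cohort(cfg: CohortConfig) -> list[PatientSeries]:
    """Generate the full synthetic cohort, reproducibly under ``cfg.seed``.

    Per-patient draws: CTV volume and fraction count (resampled from the
    emulated clinical series when ``use_table_values`` and permuted when
    ``n_patients`` matches), dose gradients, and a spatially varying
    systematic deformation field held fixed over the patient's fractions.
    Each fraction adds an independent random field and, with probability
    ``large_excursion_prob``, an outward surface excursion; the deformed
    CTV_i is the planning CTV warped through the (inverted) field.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.grid
    lo_v, hi_v = cfg.ctv_volume_range
    if cfg.use_table_values:
        vols = [v for v in TABLE_CTV_VOLUMES_CM3 if lo_v <= v <= hi_v]
        cnts = [c for c in TABLE_FRACTION_COUNTS if cfg.fractions_range[0] <= c <= cfg.fractions_range[1]]
    else:
        vols, cnts = [], []
    if len(vols) >= cfg.n_patients:
        volumes = rng.permutation(vols)[: cfg.n_patients]
    elif vols:
        volumes = rng.choice(vols, cfg.n_patients, replace=True)
    else:
        volumes = rng.uniform(lo_v, hi_v, cfg.n_patients)
    if len(cnts) >= cfg.n_patients:
        counts = rng.permutation(cnts)[: cfg.n_patients]
    elif cnts:
        counts = rng.choice(cnts, cfg.n_patients, replace=True)
    else:
        counts = rng.integers(cfg.fractions_range[0], cfg.fractions_range[1] + 1, cfg.n_patients)

    sys_point_sd = np.asarray(cfg.systematic_sd) / np.sqrt(2.0)
    rand_point_sd = np.asarray(cfg.random_sd) / np.sqrt(2.0)

    cohort = []
    for p in range(cfg.n_patients):
        pid = f"P{p:02d}"
        ctv = generate_ctv(spec, float(volumes[p]), rng)
        g_cc = rng.uniform(*cfg.gradient_cc)
        g_ax = rng.uniform(*cfg.gradient_axial)
        dose = generate_plan_dose(
            ctv, cfg.ptv_margin, cfg.prescription_dose, (g_cc, g_ax),
            boost_rate=cfg.boost_rate, boost_cap=cfg.boost_cap,
        )
        systematic = _gaussian_random_field(
            spec, sys_point_sd, cfg.correlation_length_mm, rng
        )
        surface = _surface_voxels(ctv.values)
        centroid = spec.index_to_world(np.argwhere(ctv.values).mean(axis=0))
        series = PatientSeries(
            pid, spec, ctv, dose, cfg.prescription_dose,
            n_plan_fractions=cfg.n_plan_fractions,
        )
        for _ in range(int(counts[p])):
            excursion = None
            if rng.uniform() < cfg.large_excursion_prob and len(surface):
                # excursion sites cluster at the superior/inferior CTV
                # surface (quadratic preference for cranio-caudal poles)
                dz = np.abs(spec.index_to_world(surface)[:, 0] - centroid[0])
                pw = (dz + 1.0) ** 2
                sv = surface[rng.choice(len(surface), p=pw / pw.sum())]
                center = spec.index_to_world(sv)
                direction = center - centroid
                # large deviations cluster cranio-caudally (superior/inferior
                # CTV surface), where the dose gradients are steepest
                direction[0] *= 2.0
                nrm = np.linalg.norm(direction)
                direction = direction / nrm if nrm > 0 else np.array([1.0, 0, 0])
                excursion = {
                    "center": center,
                    "direction": direction,
                    "amplitude": rng.uniform(*cfg.excursion_amplitude),
                    "sigma": cfg.excursion_sigma_mm,
                }
            fld = generate_fraction_field(
                spec,
                systematic=systematic,
                random_sd=rand_point_sd,
                correlation_length_mm=cfg.correlation_length_mm,
                excursion=excursion,
                edge_taper_mm=cfg.edge_taper_mm,
                seed=rng,
            )
            ctv_i = warp_mask_band(ctv, fld)
            if ctv_i.n_voxels == 0:
                raise RuntimeError(f"deformed CTV of {pid} vanished; field too large")
            series.fractions.append((fld, ctv_i))
        cohort.append(series)
    return cohort
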