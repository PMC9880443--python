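"""Dose-volume histograms and equivalent-uniform-dose models.

Two effectiveness measures for an inhomogeneous target dose distribution are
implemented:

* the phenomenological power-law gEUD, the generalized (power) mean of the
  voxel doses with tissue exponent ``a`` (``a = -20`` for tumor, which
  heavily weights cold spots), and
* the mechanistic cell-survival EUD (``EUD_SF``), the total uniform dose
  that yields the same clonogen survival as the actual distribution under a
  linear-quadratic model parameterized by the surviving fraction at 2 Gy
  (SF2) and alpha/beta.

SF2 is calibrated from the Poisson tumor-control condition
``TCP = exp(-N0 * SF2**n)`` so that a reference schedule (60 Gy in 2-Gy
fractions, 1e8 clonogens) gives 50% control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .grids import DoseGrid, StructureMask, _check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "DVH",
    "GEUDParams",
    "SFModelParams",
    "compute_dvh",
    "dose_percentile",
    "d_min",
    "geud",
    "calibrate_sf2",
    "eud_sf",
]


@dataclass
class DVH:
    """Cumulative dose-volume histogram of a structure.

    ``cum_volume[i]`` is the fraction of the structure volume receiving at
    least ``bin_edges[i]`` Gy; it is non-increasing and starts at 1.
    """

    bin_edges: np.ndarray
    cum_volume: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cum_volume = np.asarray(self.cum_volume, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.shape != self.cum_volume.shape:
            raise ValueError("bin_edges and cum_volume must be matching 1-D arrays")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(np.diff(self.cum_volume) > 1e-12):
            raise ValueError("cum_volume must be non-increasing")
        if not np.isclose(self.cum_volume[0], 1.0):
            raise ValueError("cum_volume must start at 1 (whole structure)")

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Representative doses and differential volume fractions.

        The volume lost between consecutive edges is attributed to the lower
        edge (the cumulative curve drops at the edge *above* a discrete dose
        level), and the residual volume still receiving >= the last edge
        sits at the last edge.  Distributions whose dose levels coincide
        with edges — uniform doses in particular — are represented exactly;
        otherwise the attribution is accurate to one bin width.
        """
        v = -np.diff(np.append(self.cum_volume, 0.0))
        return self.bin_edges.copy(), v

    def volume_at(self, dose: float) -> float:
        """Fraction of the volume receiving at least ``dose`` (step lookup)."""
        i = np.searchsorted(self.bin_edges, dose, side="right") - 1
        if i < 0:
            return 1.0
        return float(self.cum_volume[i])

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_edges, self.cum_volume]),
            delimiter=",",
            header="dose_Gy,cum_volume",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "DVH":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class GEUDParams:
    """Power-law exponent; a = -20 is the tumor value used throughout."""

    a: float = -20.0

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("gEUD exponent a must be nonzero")


@dataclass(frozen=True)
class SFModelParams:
    """Linear-quadratic survival model for the cell-survival EUD.

    sf2 is the surviving fraction after a single 2 Gy fraction; alpha_beta
    (Gy) controls the fraction-size correction; n0 clonogens of uniform
    density; the course delivers n_fractions equal fractions.
    """

    sf2: float = 0.534598229
    alpha_beta: float = 4.0
    n0: float = 1e8
    n_fractions: int = 30
    d_ref: float = 2.0
    fraction_size_correction: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.sf2 < 1):
            raise ValueError("sf2 must lie in (0, 1)")
        if self.alpha_beta <= 0 or self.n0 < 1 or self.n_fractions < 1:
            raise ValueError("invalid survival-model parameters")

    def log_survival_per_fraction(self, d: np.ndarray) -> np.ndarray:
        """log s(d) for one fraction of d Gy.

        With the fraction-size correction,
        ``s(d) = sf2 ** [(d/d_ref) * (alpha_beta + d) / (alpha_beta + d_ref)]``;
        without it, ``s(d) = sf2 ** (d / d_ref)``.
        """
        d = np.asarray(d, dtype=float)
        if self.fraction_size_correction:
            expo = (d / self.d_ref) * (self.alpha_beta + d) / (self.alpha_beta + self.d_ref)
        else:
            expo = d / self.d_ref
        return expo * np.log(self.sf2)


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float | None = None
) -> DVH:
    """Cumulative DVH over the masked voxels with equal voxel weighting.

    Parameters
    ----------
    bin_width : float, optional
        Bin width in Gy.  Defaults to 0.1% of the maximum masked dose
        (a fine binning so gEUD from binned data matches voxel-wise values).
    """
    _check_same_grid(dose, mask)
    if mask.n_voxels == 0:
        raise ValueError("cannot compute a DVH of an empty mask")
    d = dose.values[mask.values]
    dmax = float(d.max())
    if bin_width is None:
        bin_width = max(dmax * 1e-3, 1e-6)
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    # V(edge) = fraction receiving >= edge
    cum = 1.0 - np.searchsorted(np.sort(d), edges, side="left") / d.size
    cum[0] = 1.0
    return DVH(edges, cum)


def dose_percentile(dvh: DVH, x: float) -> float:
    """Dx: minimum dose received by the hottest x% of the volume.

    D100 is the minimum binned dose; monotone non-increasing in x.
    """
    if not (0 < x <= 100):
        raise ValueError("percentile x must lie in (0, 100]")
    frac = x / 100.0
    # largest dose level whose cumulative volume is still >= frac
    ok = dvh.cum_volume >= frac - 1e-12
    if not ok.any():
        return float(dvh.bin_edges[0])
    return float(dvh.bin_edges[np.nonzero(ok)[0][-1]])


def d_min(dose: DoseGrid, mask: StructureMask) -> tuple[float, tuple[int, int, int]]:
    """Minimum voxel dose inside the mask and its argmin voxel index.

    Ties are broken by the lowest linear (C-order) voxel index.
    """
    _check_same_grid(dose, mask)
    if mask.n_voxels == 0:
        raise ValueError("cannot take the minimum dose of an empty mask")
    vals = np.where(mask.values, dose.values, np.inf)
    flat = int(np.argmin(vals))  # first occurrence = lowest linear index
    idx = np.unravel_index(flat, dose.values.shape)
    return float(dose.values[idx]), tuple(int(i) for i in idx)


def geud(
    dvh: DVH, params: GEUDParams = GEUDParams(), prescription: float | None = None
) -> float:
    """Generalized EUD: power mean ``(sum_i v_i d_i**a)**(1/a)`` over the
    differential DVH, evaluated at bin midpoints.

    For a < 0 a bin at zero dose dominates completely and 0 is returned.
    If ``prescription`` is given the result is normalized by it.
    """
    mid, v = dvh.differential()
    keep = v > 0
    mid, v = mid[keep], v[keep]
    v = v / v.sum()
    a = params.a
    if a < 0 and np.any(mid <= 0):
        log.warning("zero-dose bin with a<0: gEUD collapses to 0 (complete cold spot)")
        return 0.0
    # evaluate in log space around the min/max to avoid overflow at |a|=20+
    ref = mid.min() if a < 0 else mid.max()
    val = ref * float(np.exp(np.log(np.sum(v * (mid / ref) ** a)) / a))
    return val / prescription if prescription else val


def calibrate_sf2(
    tcp_target: float, total_dose: float, dose_per_fraction: float, n0: float
) -> float:
    """Solve the Poisson TCP condition ``exp(-n0 * sf2**n) = tcp_target``
    for SF2, with ``n = total_dose / dose_per_fraction`` whole fractions.

    Closed form: ``sf2 = (ln(1/tcp) / n0) ** (dose_per_fraction / total_dose)``.
    """
    if not (0 < tcp_target < 1):
        raise ValueError("tcp_target must lie in (0, 1)")
    n = total_dose / dose_per_fraction
    if abs(n - round(n)) > 1e-9 or n < 1:
        raise ValueError("total_dose must divide into whole fractions")
    return float((np.log(1.0 / tcp_target) / n0) ** (1.0 / n))


def eud_sf(
    dvh_per_fraction: DVH,
    params: SFModelParams = SFModelParams(),
    prescription: float | None = None,
) -> float:
    """Cell-survival EUD of a whole course built by repeating one fraction.

    The per-fraction DVH (doses on the ~2 Gy per-fraction scale) is applied
    ``n_fractions`` times; course survival is
    ``S = sum_i v_i * s(d_i)**n`` and EUD_SF is the total uniform dose
    (n equal fractions) with the same S, found by monotone root-finding.
    Uniform input returns the total dose exactly.
    """
    mid, v = dvh_per_fraction.differential()
    keep = v > 0
    mid, v = mid[keep], v[keep]
    v = v / v.sum()
    n = params.n_fractions
    # log-sum-exp for numerical stability: log S
    logs = n * params.log_survival_per_fraction(mid)
    m = logs.max()
    log_s = m + np.log(np.sum(v * np.exp(logs - m)))
    if log_s >= 0:
        warnings.warn("course survival clamped at 1 (zero-dose distribution)")
        return 0.0
    # solve n*log s(du) = log_s for the uniform per-fraction dose du
    def f(du: float) -> float:
        return n * float(params.log_survival_per_fraction(du)) - log_s

    hi = max(mid.max() * 2, params.d_ref)
    while f(hi) > 0:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("EUD_SF root-finding failed to bracket")
    du = brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-14)
    total = du * n
    return total / prescription if prescription else total
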