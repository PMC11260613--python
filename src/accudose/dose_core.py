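"""EQD2 conversion, resampling, warping and EBRT+BT dose accumulation.

Combined cervical-cancer radiotherapy delivers an external-beam course (EBRT,
typically 45–50 Gy in 25 fractions) plus a brachytherapy boost (BT, several
high-dose-rate fractions).  Before the two courses can be summed voxel by
voxel they must be expressed on a common radiobiological scale — the
equivalent dose in 2 Gy fractions (EQD2) of the linear-quadratic model —
and on a common grid (the EBRT planning frame), with the BT dose mapped
there through an externally supplied deformation field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, InvalidParameterError
from .grid import DeformationField, DoseGrid, GridGeometry

__all__ = [
    "FractionationScheme",
    "eqd2_convert",
    "scale_bt_course",
    "resample_to_grid",
    "warp_dose",
    "accumulate_dose",
]

#: linear-quadratic alpha/beta ratios (Gy) used throughout the pipeline
ALPHA_BETA_TUMOR = 10.0
ALPHA_BETA_NORMAL_TISSUE = 3.0


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription of one course: total dose, fraction count, alpha/beta (Gy)."""

    total_dose: float
    n_fractions: int
    alpha_beta: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions <= 0:
            raise InvalidParameterError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if not np.isfinite(self.alpha_beta) or self.alpha_beta <= 0:
            raise InvalidParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if not np.isfinite(self.total_dose) or self.total_dose < 0:
            raise InvalidParameterError(f"total_dose must be finite and >= 0, got {self.total_dose}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def eqd2_convert(dose: DoseGrid, scheme: FractionationScheme) -> DoseGrid:
    """Convert a physical dose grid to EQD2 under the linear-quadratic model.

    Each voxel holds the total physical dose D delivered in
    ``scheme.n_fractions`` equal fractions, so the per-voxel fraction dose is
    ``d = D / n_fractions`` and

        EQD2 = D * (d + alpha/beta) / (2 + alpha/beta).

    Zero-dose voxels stay zero and the grid geometry is unchanged.  A course
    delivered at exactly 2 Gy per fraction is a fixed point.
    """
    ab = scheme.alpha_beta
    d = dose.values / scheme.n_fractions
    # factor first: keeps the 2 Gy/fraction fixed point exact in floating point
    return dose.with_values(dose.values * ((d + ab) / (2.0 + ab)))


def scale_bt_course(bt_fraction_eqd2: DoseGrid, n_bt_fractions: int) -> DoseGrid:
    """Scale a single-fraction BT EQD2 grid to the full course.

    EQD2 is additive over identical fractions, so a course of n identical
    fractions is n times the per-fraction EQD2 — the "magnify the first
    fraction" surrogate used when only the first BT fraction is planned on CT.
    """
    if int(n_bt_fractions) != n_bt_fractions or n_bt_fractions < 1:
        raise InvalidParameterError(f"n_bt_fractions must be an integer >= 1, got {n_bt_fractions}")
    return bt_fraction_eqd2.with_values(bt_fraction_eqd2.values * float(n_bt_fractions))


def _require_overlap(src: GridGeometry, dst: GridGeometry) -> None:
    for (a0, a1), (b0, b1) in zip(src.extent_mm(), dst.extent_mm()):
        if a1 < b0 or b1 < a0:
            raise GeometryError("source and target grids have disjoint physical extents")


def _sample_trilinear(dose: DoseGrid, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of a dose grid at physical points (..., 3); outside -> 0."""
    geom = dose.geometry
    idx = np.empty_like(points_mm)
    for a in range(3):
        idx[..., a] = (points_mm[..., a] - geom.origin[a]) / geom.spacing[a]
    coords = np.moveaxis(idx, -1, 0)
    return map_coordinates(dose.values, coords, order=1, mode="constant", cval=0.0)


def resample_to_grid(dose: DoseGrid, target_geometry: GridGeometry) -> DoseGrid:
    """Trilinear resampling onto a target geometry; outside the source extent -> 0."""
    _require_overlap(dose.geometry, target_geometry)
    cx, cy, cz = target_geometry.voxel_centers_mm()
    pts = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)
    vals = _sample_trilinear(dose, pts)
    # trilinear interpolation of non-negative data can only go negative through
    # floating rounding; clip to preserve the DoseGrid invariant
    return DoseGrid(values=np.clip(vals, 0.0, None), geometry=target_geometry)


def warp_dose(dose: DoseGrid, dvf: DeformationField) -> DoseGrid:
    """Warp a dose grid onto the field's reference grid.

    The field stores pull-back displacements: the output voxel at reference
    center ``c`` takes the trilinear sample of ``dose`` at ``c + dvf(c)``.
    Samples falling outside the source extent are 0.
    """
    geom = dvf.geometry
    cx, cy, cz = geom.voxel_centers_mm()
    centers = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)
    vals = _sample_trilinear(dose, centers + dvf.vectors)
    return DoseGrid(values=np.clip(vals, 0.0, None), geometry=geom)


def accumulate_dose(ebrt_eqd2: DoseGrid, bt_total_eqd2_warped: DoseGrid) -> DoseGrid:
    """Voxel-wise sum of the EBRT and (warped, course-scaled) BT EQD2 grids."""
    ebrt_eqd2.geometry.require_same_grid(bt_total_eqd2_warped.geometry, check_frame=True)
    return ebrt_eqd2.with_values(ebrt_eqd2.values + bt_total_eqd2_warped.values)
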