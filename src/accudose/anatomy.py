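"""Anatomical input channels and the isodose-overlap replanning aid.

The dose-prediction model sees three channels per axial slice: the planning
CT, a structure label map, and a distance-to-target (DTT) map.  The label
map assigns each target/OAR a base label and sums labels on overlapping
voxels so every combination of structures remains uniquely decodable; the
DTT map holds the minimum distance (mm) from the PTV surface for every
normal-tissue voxel.  This module also builds the overlap between a
predicted isodose volume and an OAR, the avoidance contour used to redesign
the external-beam plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import (
    GeometryError,
    InvalidParameterError,
    InvalidStructureError,
    LabelCollisionError,
)
from .grid import DoseGrid, GridGeometry, StructureSet

__all__ = [
    "LabelMap",
    "DTTMap",
    "default_label_table",
    "build_structure_label_map",
    "decode_label",
    "compute_dtt_map",
    "override_ct_numbers",
    "isodose_volume",
    "overlap_contour",
]

#: voxels outside the body
EXTERIOR_LABEL = 0
#: body voxels belonging to no target/OAR
BODY_LABEL = 1


@dataclass(frozen=True)
class LabelMap:
    """Integer structure map with its name -> base-label assignment."""

    values: np.ndarray
    assignment: dict[str, int]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.geometry.shape:
            raise GeometryError(f"label array shape {vals.shape} != {self.geometry.shape}")
        object.__setattr__(self, "values", vals.astype(np.int64))

    @property
    def max_label(self) -> int:
        return int(self.values.max())


@dataclass(frozen=True)
class DTTMap:
    """Distance-to-target map: mm from the PTV surface, 0 inside PTV/outside body."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.geometry.shape:
            raise GeometryError(f"DTT array shape {vals.shape} != {self.geometry.shape}")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InvalidParameterError("DTT values must be finite and >= 0")
        object.__setattr__(self, "values", vals)


def default_label_table(structures: StructureSet) -> dict[str, int]:
    """Powers of two starting at 2, assigned in the set's insertion order.

    The body background reserves 1 and the exterior 0, so structure labels
    start at 2; distinct powers of two make every overlap sum unique.
    """
    table: dict[str, int] = {}
    label = 2
    for name in structures.names():
        if name == "body":
            continue
        table[name] = label
        label *= 2
    return table


def _check_decodable(structures: StructureSet, table: dict[str, int]) -> None:
    """Reject label tables whose observed overlap sums collide."""
    labels = list(table.items())
    stack = np.stack([structures[name] for name, _ in labels], axis=0)
    base = np.asarray([lab for _, lab in labels], dtype=np.int64)
    flat = stack.reshape(len(labels), -1)
    combos = {tuple(col) for col in flat.T[np.any(flat.T, axis=1)]}
    sums: dict[int, tuple] = {}
    for combo in combos:
        s = int(np.dot(base, combo))
        if s <= BODY_LABEL:
            raise LabelCollisionError(f"label sum {s} collides with a reserved background label")
        if s in sums and sums[s] != combo:
            raise LabelCollisionError(
                f"structure combinations {sums[s]} and {combo} both sum to label {s}"
            )
        sums[s] = combo


def build_structure_label_map(
    structures: StructureSet, label_table: dict[str, int] | None = None
) -> LabelMap:
    """Sum base labels per voxel into a uniquely decodable structure map.

    Voxels outside the body get 0, body-only voxels get 1, and a voxel inside
    several structures gets the sum of their base labels.  With the default
    power-of-two table the sum is injective for arbitrary overlaps; custom
    tables are checked against every overlap combination actually present.
    """
    structures.require("body")
    if label_table is None:
        label_table = default_label_table(structures)
    else:
        for name in label_table:
            structures.require(name)
        if any(lab < 2 for lab in label_table.values()):
            raise LabelCollisionError("base labels must be >= 2 (0/1 are reserved)")
    _check_decodable(structures, label_table)

    values = np.where(structures["body"], BODY_LABEL, EXTERIOR_LABEL).astype(np.int64)
    summed = np.zeros_like(values)
    for name, label in label_table.items():
        summed += label * structures[name].astype(np.int64)
    values = np.where(summed > 0, summed, values)
    return LabelMap(values=values, assignment=dict(label_table), geometry=structures.geometry)


def decode_label(value: int, assignment: dict[str, int]) -> frozenset[str]:
    """Recover the set of structures containing a voxel from its label value."""
    if value == EXTERIOR_LABEL or value == BODY_LABEL:
        return frozenset()
    remaining = int(value)
    members = []
    for name, label in sorted(assignment.items(), key=lambda kv: -kv[1]):
        if remaining >= label:
            members.append(name)
            remaining -= label
    if remaining != 0:
        raise LabelCollisionError(f"label value {value} is not decodable under {assignment}")
    return frozenset(members)


def compute_dtt_map(structures: StructureSet) -> DTTMap:
    """Euclidean distance (mm) from each normal-tissue voxel to the nearest PTV voxel.

    Anisotropic voxel spacing is respected; voxels inside the PTV and outside
    the body are 0 by definition.
    """
    structures.require("body", "ptv")
    ptv = structures["ptv"]
    if not ptv.any():
        raise InvalidStructureError("PTV mask is empty")
    dist = distance_transform_edt(~ptv, sampling=structures.geometry.spacing)
    dist[~structures["body"]] = 0.0
    return DTTMap(values=dist, geometry=structures.geometry)


def override_ct_numbers(
    image: np.ndarray,
    structures: StructureSet,
    values: dict[str, float],
) -> np.ndarray:
    """Set the CT number inside each named structure to a fixed intensity.

    Used to homogenise applicator/packing intensities before registration.
    Structures are applied in the order listed, so on overlapping masks the
    later entry wins; all other voxels are unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != structures.geometry.shape:
        raise GeometryError(f"image shape {img.shape} != grid shape {structures.geometry.shape}")
    out = img.copy()
    for name, value in values.items():
        out[structures[name]] = float(value)
    return out


def isodose_volume(dose: DoseGrid, level: float) -> np.ndarray:
    """Binary mask of voxels receiving at least ``level`` Gy (inclusive)."""
    if not np.isfinite(level) or level <= 0:
        raise InvalidParameterError(f"isodose level must be > 0, got {level}")
    return dose.values >= level


def overlap_contour(predicted: DoseGrid, level: float, oar_mask: np.ndarray) -> np.ndarray:
    """Intersection of a predicted isodose volume with an OAR mask.

    This is the avoidance contour of the replanning step: the region of the
    bladder/rectum expected to exceed ``level`` Gy, in which the redesigned
    external-beam plan should suppress hotspots.
    """
    oar = np.asarray(oar_mask, dtype=bool)
    if oar.shape != predicted.geometry.shape:
        raise GeometryError(f"OAR mask shape {oar.shape} != grid shape {predicted.geometry.shape}")
    return isodose_volume(predicted, level) & oar
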