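"""Grid-aligned volume containers and file I/O.

All volumes in the package live on regular 3-D grids indexed ``(x, y, z)``.
The physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
(voxel centers, 0-based indices, millimetres); doses are in Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import GeometryError, InvalidParameterError, InvalidStructureError

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "DeformationField",
    "StructureSet",
    "load_volume_nifti",
    "save_volume_nifti",
    "load_dose_nifti",
    "save_dose_nifti",
    "load_structure_set",
    "save_structure_set",
    "read_dicom_rt_dose",
    "read_dicom_rt_struct",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing (mm) and origin (mm) of a regular voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GeometryError(f"grid shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing components must be > 0, got {self.spacing}")
        if len(self.origin) != 3 or any(not np.isfinite(o) for o in self.origin):
            raise InvalidParameterError(f"origin must be finite, got {self.origin}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Per-axis [first center, last center] physical extent."""
        return tuple(
            (self.origin[a], self.origin[a] + (self.shape[a] - 1) * self.spacing[a])
            for a in range(3)
        )

    def same_grid(self, other: "GridGeometry", *, check_frame: bool = False) -> bool:
        ok = (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )
        if check_frame:
            ok = ok and self.frame_id == other.frame_id
        return ok

    def require_same_grid(self, other: "GridGeometry", *, check_frame: bool = False) -> None:
        if not self.same_grid(other, check_frame=check_frame):
            raise GeometryError(f"grid geometry mismatch: {self} vs {other}")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D scalar absorbed/EQD2 dose field (Gy) on a regular grid."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.geometry.shape:
            raise GeometryError(
                f"dose array shape {vals.shape} != grid shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("dose values must be finite")
        if np.any(vals < 0):
            raise InvalidParameterError("dose values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def frame_id(self) -> str:
        return self.geometry.frame_id

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """New grid with the same geometry and different values."""
        return DoseGrid(values=values, geometry=self.geometry)

    def max(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class DeformationField:
    """Pull-back displacement vectors (mm) on the reference grid.

    ``vectors[i, j, k]`` maps the center of reference voxel ``(i, j, k)`` to
    the physical point in the source frame from which dose is sampled.
    """

    vectors: np.ndarray  # shape (*geometry.shape, 3), mm
    geometry: GridGeometry

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=np.float64)
        if vec.shape != (*self.geometry.shape, 3):
            raise GeometryError(
                f"field shape {vec.shape} != {(*self.geometry.shape, 3)}"
            )
        if not np.all(np.isfinite(vec)):
            raise InvalidParameterError("displacement components must be finite")
        object.__setattr__(self, "vectors", vec)

    @classmethod
    def identity(cls, geometry: GridGeometry) -> "DeformationField":
        return cls(np.zeros((*geometry.shape, 3)), geometry)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry.

    A ``body`` mask is mandatory; every other mask must be a subset of it.
    """

    geometry: GridGeometry
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "body" not in self.masks:
            raise InvalidStructureError("a StructureSet requires a 'body' mask")
        clean: dict[str, np.ndarray] = {}
        body = np.asarray(self.masks["body"], dtype=bool)
        for name, mask in self.masks.items():
            arr = np.asarray(mask, dtype=bool)
            if arr.shape != self.geometry.shape:
                raise GeometryError(
                    f"mask '{name}' shape {arr.shape} != grid shape {self.geometry.shape}"
                )
            if name != "body" and np.any(arr & ~body):
                raise InvalidStructureError(f"mask '{name}' extends outside the body")
            clean[name] = arr
        self.masks = clean

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise InvalidStructureError(f"unknown structure '{name}'") from None

    def names(self) -> Iterator[str]:
        return iter(self.masks)

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.masks:
                raise InvalidStructureError(f"structure '{name}' is required but missing")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _nibabel():
    import nibabel as nib

    return nib


def save_volume_nifti(values: np.ndarray, geometry: GridGeometry, path: str | Path) -> None:
    nib = _nibabel()
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), geometry.affine())
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path, frame_id: str = "") -> tuple[np.ndarray, GridGeometry]:
    """Load a NIfTI volume; spacing/origin come from the (diagonal) affine."""
    nib = _nibabel()
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.max(np.abs(rot)) > 1e-6:
        raise GeometryError(f"{path}: only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(abs(aff[a, a])) for a in range(3))
    origin = tuple(float(aff[a, 3]) for a in range(3))
    data = np.asarray(img.dataobj, dtype=np.float64)
    # 4-D volumes (e.g. displacement fields) keep their trailing axis; the
    # grid geometry always describes the first three
    geom = GridGeometry(shape=data.shape[:3], spacing=spacing, origin=origin, frame_id=frame_id)
    return data, geom


def save_dose_nifti(dose: DoseGrid, path: str | Path) -> None:
    save_volume_nifti(dose.values, dose.geometry, path)


def load_dose_nifti(path: str | Path, frame_id: str = "") -> DoseGrid:
    data, geom = load_volume_nifti(path, frame_id)
    return DoseGrid(values=data, geometry=geom)


def save_structure_set(structures: StructureSet, directory: str | Path) -> Path:
    """Write one NIfTI mask per structure plus a JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, mask in structures.masks.items():
        fname = f"{name}.nii.gz"
        save_volume_nifti(mask.astype(np.uint8), structures.geometry, directory / fname)
        entries.append({"name": name, "file": fname})
    manifest = directory / "structures.json"
    manifest.write_text(json.dumps({"structures": entries}, indent=2))
    return manifest


def load_structure_set(manifest_path: str | Path, frame_id: str = "") -> StructureSet:
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    masks: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    for entry in spec["structures"]:
        data, g = load_volume_nifti(manifest_path.parent / entry["file"], frame_id)
        if geom is None:
            geom = g
        else:
            geom.require_same_grid(g)
        masks[entry["name"]] = data > 0.5
    if geom is None:
        raise InvalidStructureError(f"{manifest_path}: empty structure manifest")
    return StructureSet(geometry=geom, masks=masks)


# ---------------------------------------------------------------------------
# DICOM RT Dose import
# ---------------------------------------------------------------------------

def read_dicom_rt_dose(path: str | Path, frame_id: str = "") -> DoseGrid:
    """Import a DICOM RT Dose file (DoseGridScaling applied).

    The DICOM frame stack (frames, rows, cols) is reordered to the package's
    (x, y, z) axis convention; the slice spacing comes from
    GridFrameOffsetVector, which must be uniform.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    raw = ds.pixel_array.astype(np.float64) * scaling  # (z, y, x)
    values = np.transpose(raw, (2, 1, 0))
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row -> y, col -> x
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) == 0 or not np.allclose(dz, dz[0]):
        raise GeometryError(f"{path}: non-uniform GridFrameOffsetVector is unsupported")
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    geom = GridGeometry(
        shape=values.shape,
        spacing=(col_sp, row_sp, float(abs(dz[0]))),
        origin=origin,
        frame_id=frame_id,
    )
    return DoseGrid(values=values, geometry=geom)


def read_dicom_rt_struct(path: str | Path, geometry: GridGeometry) -> dict[str, np.ndarray]:
    """Rasterize a DICOM RT Structure Set onto a reference grid.

    Each CLOSED_PLANAR contour is assigned to the nearest axial slice and
    filled by a point-in-polygon test on voxel centers; multiple contours of
    one ROI are OR-combined (holes are not subtracted).  Returns a mapping
    of ROI name to boolean mask; assembling a :class:`StructureSet` (with a
    body mask) is left to the caller.
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    cx, cy, _ = geometry.voxel_centers_mm()
    grid_xy = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)

    masks: dict[str, np.ndarray] = {}
    for roi_contour in ds.ROIContourSequence:
        name = names[int(roi_contour.ReferencedROINumber)]
        mask = masks.setdefault(name, np.zeros(geometry.shape, dtype=bool))
        for contour in getattr(roi_contour, "ContourSequence", []):
            if str(getattr(contour, "ContourGeometricType", "")) != "CLOSED_PLANAR":
                continue
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            k = int(round((float(pts[:, 2].mean()) - geometry.origin[2]) / geometry.spacing[2]))
            if not 0 <= k < geometry.shape[2]:
                continue
            inside = MplPath(pts[:, :2]).contains_points(grid_xy)
            mask[:, :, k] |= inside.reshape(geometry.shape[:2])
    return masks
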