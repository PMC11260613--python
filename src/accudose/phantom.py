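"""Seeded synthetic pelvic phantoms with analytic EBRT+BT accumulated dose.

Each phantom emulates one cervical-cancer patient at planning time: an
elliptical body with a bony rim, an anterior bladder, a posterior rectum, a
central uterus+vagina (U+V) holding the brachytherapy applicator, and a PTV
obtained by dilating the U+V.  The ground-truth accumulated dose is built
analytically in the EQD2 frame as

* an EBRT term: the prescription EQD2 (45 Gy / 25 fx at alpha/beta 10 by
  default) times a Gaussian-smoothed PTV indicator (the penumbra), plus
* a BT term: the course EQD2 of the boost (4 x 6 Gy fractions) scaled by an
  inverse-square kernel around dwell points on the central applicator line,
  normalised to the prescription at a 20 mm lateral reference radius and
  capped at a ceiling.

Dose is therefore a deterministic, learnable function of anatomy, with the
steep central gradients that make accumulated-dose prediction non-trivial.
This is deliberately NOT source dosimetry (no TG-43): it exists to exercise
the pipeline, not to model an afterloader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .dose_core import FractionationScheme, accumulate_dose, eqd2_convert, scale_bt_course
from .errors import ConfigurationError, GeometryError, InvalidParameterError
from .grid import (
    DeformationField,
    DoseGrid,
    GridGeometry,
    StructureSet,
    save_dose_nifti,
    save_structure_set,
    save_volume_nifti,
)

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_cohort", "simulate_redesign"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, prescription and variability of the synthetic cohort.

    Distances are mm, doses Gy, intensities HU.  The U+V sits at the
    (jittered) body center and the bladder/rectum are packed against its
    surface; per-patient jitter perturbs centers (uniform, +- mm), radii
    (uniform, +- fraction) and the organ gaps.
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)

    # anatomy (semi-axes in mm).  The bladder (anterior) and rectum
    # (posterior) are packed against the jittered U+V surface with a small
    # random gap, the way pelvic organs actually sit against the cervix.
    body_semiaxes_mm: tuple[float, float] = (115.0, 95.0)
    uv_semiaxes_mm: tuple[float, float, float] = (18.0, 14.0, 45.0)
    bladder_semiaxes_mm: tuple[float, float, float] = (26.0, 18.0, 24.0)
    rectum_semiaxes_mm: tuple[float, float, float] = (11.0, 12.0, 50.0)
    organ_gap_mm_range: tuple[float, float] = (1.0, 3.0)
    # the EBRT target is whole-pelvis-like: wide enough that the abutting
    # bladder/rectum walls sit deep inside the prescription plateau
    ptv_margin_mm: float = 18.0
    center_jitter_mm: float = 4.0
    radius_jitter_frac: float = 0.12
    max_retries: int = 5

    # prescriptions
    ebrt_total_gy: float = 45.0
    ebrt_fractions: int = 25
    bt_fraction_gy: float = 6.0
    bt_fractions: int = 4
    alpha_beta_tumor: float = 10.0

    # BT line-source surrogate
    n_dwell: int = 7
    dwell_spacing_mm: float = 10.0
    bt_ref_radius_mm: float = 20.0
    bt_min_radius_mm: float = 3.0
    hotspot_cap_gy: float = 160.0

    # image model / replanning surrogate
    penumbra_sigma_mm: float = 6.0
    # a replanned VMAT arc lowers dose in a broad region around the avoidance
    # contour, not just inside it; the reduction ramps linearly to zero over
    # this distance outside the contour
    redesign_falloff_mm: float = 30.0
    noise_sigma_hu: float = 20.0
    dvf_amplitude_mm: float = 3.0
    dvf_smoothing_mm: float = 12.0

    # tissue-class CT numbers
    hu_values: dict = field(
        default_factory=lambda: {
            "air": -1000.0, "soft": 40.0, "bone": 700.0,
            "bladder": 15.0, "rectum": -80.0, "uterus_vagina": 45.0,
        }
    )

    def __post_init__(self) -> None:
        if self.ebrt_total_gy <= 0 or self.bt_fraction_gy < 0:
            raise InvalidParameterError("prescriptions must be positive")
        if self.bt_fractions < 1 or self.ebrt_fractions < 1:
            raise InvalidParameterError("fraction counts must be >= 1")

    @property
    def ebrt_plateau_eqd2_gy(self) -> float:
        """EQD2 of the EBRT prescription (44.25 Gy for 45 Gy / 25 fx, a/b 10)."""
        d = self.ebrt_total_gy / self.ebrt_fractions
        return self.ebrt_total_gy * (d + self.alpha_beta_tumor) / (2.0 + self.alpha_beta_tumor)

    @property
    def bt_course_eqd2_gy(self) -> float:
        """Course EQD2 of the BT boost at the reference radius (32 Gy default)."""
        ab = self.alpha_beta_tumor
        per_fraction = self.bt_fraction_gy * (self.bt_fraction_gy + ab) / (2.0 + ab)
        return self.bt_fractions * per_fraction

    @property
    def summed_prescription_eqd2_gy(self) -> float:
        return self.ebrt_plateau_eqd2_gy + self.bt_course_eqd2_gy


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic patient with its ground-truth accumulated EQD2 dose."""

    ct: np.ndarray
    structures: StructureSet
    truth_dose: DoseGrid
    ebrt_dose: DoseGrid
    bt_dose: DoseGrid
    dvf: DeformationField
    seed: int
    spec: PhantomSpec

    @property
    def geometry(self) -> GridGeometry:
        return self.structures.geometry


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Build one phantom, fully reproducible from ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    geom = GridGeometry(
        shape=spec.shape, spacing=spec.spacing, origin=(0.0, 0.0, 0.0), frame_id=f"phantom-{seed}"
    )
    cx, cy, cz = geom.voxel_centers_mm()
    coords = np.meshgrid(cx, cy, cz, indexing="ij")
    body_center = (
        (cx[0] + cx[-1]) / 2.0, (cy[0] + cy[-1]) / 2.0, (cz[0] + cz[-1]) / 2.0,
    )
    z_extent = (cz[0], cz[-1])

    ax, ay = spec.body_semiaxes_mm
    rho2 = ((coords[0] - body_center[0]) / ax) ** 2 + ((coords[1] - body_center[1]) / ay) ** 2
    body = rho2 <= 1.0

    # organ placement with jitter; retry when an organ would leave the body
    def place(rng) -> dict | None:
        jc, jr = spec.center_jitter_mm, spec.radius_jitter_frac
        uv_c = tuple(bc + rng.uniform(-jc, jc) for bc in body_center)
        uv_s = tuple(s * (1.0 + rng.uniform(-jr, jr)) for s in spec.uv_semiaxes_mm)
        trial = {"uterus_vagina": (uv_c, uv_s)}
        for name, semiaxes, side in (
            ("bladder", spec.bladder_semiaxes_mm, -1.0),
            ("rectum", spec.rectum_semiaxes_mm, +1.0),
        ):
            s = tuple(si * (1.0 + rng.uniform(-jr, jr)) for si in semiaxes)
            gap = rng.uniform(*spec.organ_gap_mm_range)
            c = (
                uv_c[0] + rng.uniform(-jc, jc),
                uv_c[1] + side * (uv_s[1] + gap + s[1]),
                uv_c[2] + rng.uniform(-jc, jc),
            )
            trial[name] = (c, s)
        for c, s in trial.values():
            # organs may protrude past the image top/bottom (a rectum does);
            # only the in-plane body boundary is enforced
            if (
                abs(c[0] - body_center[0]) + s[0] > 0.98 * ax
                or abs(c[1] - body_center[1]) + s[1] > 0.98 * ay
            ):
                return None
        return trial

    placed = None
    for _ in range(max(1, spec.max_retries)):
        placed = place(rng)
        if placed is not None:
            break
    if placed is None:
        raise GeometryError("organs do not fit inside the body after jitter retries")

    masks = {"body": body}
    for name, (c, s) in placed.items():
        masks[name] = _ellipsoid(coords, c, s) & body

    uv = masks["uterus_vagina"]
    dist_to_uv = distance_transform_edt(~uv, sampling=geom.spacing)
    masks["ptv"] = (dist_to_uv <= spec.ptv_margin_mm) & body
    structures = StructureSet(geometry=geom, masks=masks)

    # CT: tissue classes + Gaussian noise inside the body
    hu = spec.hu_values
    ct = np.full(geom.shape, hu["air"])
    ct[body] = hu["soft"]
    rim = (rho2 >= 0.88**2) & (rho2 <= 0.97**2)
    ct[rim & body] = hu["bone"]
    for name in ("bladder", "rectum", "uterus_vagina"):
        ct[masks[name]] = hu[name]
    if spec.noise_sigma_hu > 0:
        ct[body] += rng.normal(0.0, spec.noise_sigma_hu, size=int(body.sum()))

    # EBRT term: prescription EQD2 times the smoothed PTV indicator
    scheme = FractionationScheme(spec.ebrt_total_gy, spec.ebrt_fractions, spec.alpha_beta_tumor)
    ebrt_physical = spec.ebrt_total_gy * masks["ptv"].astype(np.float64)
    if spec.penumbra_sigma_mm > 0:
        sigma_vox = [spec.penumbra_sigma_mm / s for s in geom.spacing]
        ebrt_physical = np.clip(gaussian_filter(ebrt_physical, sigma=sigma_vox), 0.0, None)
    ebrt = eqd2_convert(DoseGrid(values=ebrt_physical, geometry=geom), scheme)

    # BT term: inverse-square dwell-line kernel, prescribed at the lateral
    # reference radius, converted per fraction and scaled to the course
    uv_center, uv_semi = placed["uterus_vagina"]
    half = (spec.n_dwell - 1) / 2.0
    dwell_z = uv_center[2] + (np.arange(spec.n_dwell) - half) * spec.dwell_spacing_mm
    dwell_z = np.clip(dwell_z, uv_center[2] - uv_semi[2], uv_center[2] + uv_semi[2])

    def dwell_sum(px, py, pz):
        total = 0.0
        for zd in dwell_z:
            r2 = (px - uv_center[0]) ** 2 + (py - uv_center[1]) ** 2 + (pz - zd) ** 2
            total = total + 1.0 / np.maximum(r2, spec.bt_min_radius_mm**2)
        return total

    s_ref = dwell_sum(uv_center[0] + spec.bt_ref_radius_mm, uv_center[1], uv_center[2])
    kernel = dwell_sum(*coords) / s_ref
    ab = spec.alpha_beta_tumor
    per_fraction_physical = DoseGrid(values=spec.bt_fraction_gy * kernel, geometry=geom)
    per_fraction_eqd2 = eqd2_convert(per_fraction_physical, FractionationScheme(spec.bt_fraction_gy, 1, ab)) \
        if spec.bt_fraction_gy > 0 else per_fraction_physical
    bt = scale_bt_course(per_fraction_eqd2, spec.bt_fractions)
    bt = bt.with_values(np.minimum(bt.values, spec.hotspot_cap_gy))

    truth = accumulate_dose(ebrt, bt)

    # small smooth DVF, the stand-in for an external registration output
    noise = rng.normal(0.0, 1.0, size=(*geom.shape, 3))
    sigma_vox = [spec.dvf_smoothing_mm / s for s in geom.spacing] + [0.0]
    smooth = gaussian_filter(noise, sigma=sigma_vox)
    peak = np.abs(smooth).max()
    vectors = smooth * (spec.dvf_amplitude_mm / peak) if peak > 0 else smooth
    dvf = DeformationField(vectors=vectors, geometry=geom)

    return PhantomCase(
        ct=ct, structures=structures, truth_dose=truth, ebrt_dose=ebrt, bt_dose=bt,
        dvf=dvf, seed=int(seed), spec=spec,
    )


def child_seeds(root_seed: int, n: int) -> np.ndarray:
    """Per-patient seeds derived deterministically from one root seed."""
    return np.random.default_rng(root_seed).integers(0, 2**31 - 1, size=n)


def generate_cohort(
    spec: PhantomSpec, n_patients: int, root_seed: int, out_dir: str | Path | None = None
) -> list[PhantomCase]:
    """Generate a jittered cohort; optionally write volumes and a manifest."""
    if n_patients < 1:
        raise ConfigurationError(f"n_patients must be >= 1, got {n_patients}")
    seeds = child_seeds(root_seed, n_patients)
    cases = [generate_phantom(spec, int(s)) for s in seeds]
    if out_dir is not None:
        _write_cohort(cases, spec, root_seed, Path(out_dir))
    return cases


def _write_cohort(cases: list[PhantomCase], spec: PhantomSpec, root_seed: int, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, case in enumerate(cases):
        pdir = out_dir / f"patient_{i:03d}"
        pdir.mkdir(parents=True, exist_ok=True)
        save_volume_nifti(case.ct, case.geometry, pdir / "ct.nii.gz")
        save_dose_nifti(case.truth_dose, pdir / "truth_dose.nii.gz")
        save_dose_nifti(case.ebrt_dose, pdir / "ebrt_dose.nii.gz")
        save_dose_nifti(case.bt_dose, pdir / "bt_dose.nii.gz")
        save_structure_set(case.structures, pdir / "structures")
        entries.append({"patient": f"patient_{i:03d}", "seed": case.seed})
    manifest = {
        "root_seed": int(root_seed),
        "n_patients": len(cases),
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "patients": entries,
    }
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=2))


def simulate_redesign(case: PhantomCase, avoid_mask: np.ndarray, reduction: float) -> DoseGrid:
    """Analytic stand-in for replanning: suppress EBRT dose in an avoidance region.

    The EBRT component is scaled by ``1 - reduction * s`` where ``s`` is 1
    inside the avoidance mask and ramps linearly to 0 over the spec's
    falloff distance outside it (a replanned arc lowers dose in a broad
    neighbourhood of the hotspot, not just inside the contour), then
    re-accumulated with the unchanged BT component.  Dose never increases
    anywhere and is untouched beyond the falloff-dilated mask.
    """
    if not 0.0 < reduction < 1.0:
        raise InvalidParameterError(f"reduction must be in (0, 1), got {reduction}")
    mask = np.asarray(avoid_mask, dtype=bool)
    if mask.shape != case.geometry.shape:
        raise GeometryError(f"avoid mask shape {mask.shape} != grid shape {case.geometry.shape}")
    if not mask.any():
        return case.truth_dose
    spec = case.spec
    dist = distance_transform_edt(~mask, sampling=case.geometry.spacing)
    s = np.clip(1.0 - dist / max(spec.redesign_falloff_mm, 1e-6), 0.0, 1.0)
    new_ebrt = case.ebrt_dose.with_values(case.ebrt_dose.values * (1.0 - reduction * s))
    return accumulate_dose(new_ebrt, case.bt_dose)
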