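"""Synthetic pelvic phantom cohort.

Generates seeded digital patients that stand in for a scanned FDG-PET-MR
cohort: a stacked-2D HU volume of an elliptical torso with fat rim, pelvic
bone surrogates and internal air pockets; an activity-truth volume in SUV
units carrying spherical hot lesions (primary and nodal); manual tumour
volumes enclosing each lesion; and weight / injected-dose metadata.

Two controlled degradations of the anatomy are provided:

* :func:`degrade_to_mrac_labels` — a Dixon-style four-class segmentation in
  which bone is indistinguishable from soft tissue (the standard vendor MRAC
  failure mode in the pelvis),
* :func:`make_sct_hu` — a synthetic-CT-like HU volume whose only departures
  from the ground-truth CT are a bone HU bias and a morphological shift of
  the bone boundary.

All randomness flows from explicit integer seeds; identical (spec, seed)
pairs produce bit-identical volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import PlacementError

# --------------------------------------------------------------------------
# Tissue label codes
# --------------------------------------------------------------------------

EXTERNAL_AIR = 0
FAT = 1
SOFT_TISSUE = 2
BONE = 3
AIR_POCKET = 4

LABEL_NAMES = {
    EXTERNAL_AIR: "external_air",
    FAT: "fat",
    SOFT_TISSUE: "soft_tissue",
    BONE: "bone",
    AIR_POCKET: "air_pocket",
}

#: Default HU per tissue class (typical CT values; configurable per spec).
DEFAULT_HU = {
    EXTERNAL_AIR: -1000.0,
    FAT: -90.0,
    SOFT_TISSUE: 40.0,
    BONE: 700.0,
    AIR_POCKET: -1000.0,
}

# MRAC classes (pelvic field of view: lung never present)
MR_AIR = 0
MR_FAT = 1
MR_SOFT_TISSUE = 2

MRAC_CLASS_NAMES = {MR_AIR: "air", MR_FAT: "fat", MR_SOFT_TISSUE: "soft_tissue"}


# --------------------------------------------------------------------------
# Specification dataclasses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BodyGeometry:
    """Superelliptical torso cross-section, constant over slices.

    ``|x/a|^p + |y/b|^p <= 1`` defines the body; a rim of ``fat_thickness_mm``
    just inside the contour is subcutaneous fat.
    """

    semi_axis_x_mm: float = 160.0
    semi_axis_y_mm: float = 110.0
    exponent: float = 2.5
    fat_thickness_mm: float = 9.0


@dataclass(frozen=True)
class BoneSite:
    """In-plane circular bone surrogate extended through all slices."""

    center_mm: tuple[float, float]  # (x, y) relative to grid centre
    radius_mm: float
    hu_mean: float = 700.0
    hu_spread: float = 50.0
    name: str = "bone"


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    peak_suv: float
    kind: str  # "primary" | "nodal"


@dataclass(frozen=True)
class AirPocket:
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one digital patient."""

    grid_shape: tuple[int, int, int] = (128, 128, 9)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_geometry: BodyGeometry = field(default_factory=BodyGeometry)
    bone_sites: tuple[BoneSite, ...] = ()
    lesion_specs: tuple[LesionSpec, ...] = ()
    air_pockets: tuple[AirPocket, ...] = ()
    background_suv: float = 1.0
    fat_uptake_fraction: float = 0.6  # fat SUV relative to soft tissue
    lesion_falloff_mm: float = 3.0  # linear margin outside the plateau
    manual_margin_mm: float = 6.0  # manual volume radius beyond the plateau
    weight_kg: float = 80.0
    injected_dose_MBq: float = 280.0
    hu_noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be strictly positive")
        for b in self.bone_sites:
            if b.radius_mm <= 0:
                raise ValueError(f"bone radius must be positive: {b}")
            if not self._inside_body(b.center_mm[0], b.center_mm[1]):
                raise PlacementError(f"bone site outside body: {b}")
        for les in self.lesion_specs:
            if les.diameter_mm <= 0:
                raise ValueError(f"lesion diameter must be positive: {les}")
            if les.peak_suv <= self.background_suv:
                raise ValueError(
                    f"lesion peak SUV {les.peak_suv} must exceed background "
                    f"{self.background_suv}"
                )
            if not self._inside_body(les.center_mm[0], les.center_mm[1]):
                raise PlacementError(f"lesion centre outside body: {les}")
        for p in self.air_pockets:
            if p.radius_mm <= 0:
                raise ValueError(f"air pocket radius must be positive: {p}")
            if not self._inside_body(p.center_mm[0], p.center_mm[1]):
                raise PlacementError(f"air pocket outside body: {p}")
        if self.background_suv <= 0:
            raise ValueError("background_suv must be positive")
        # manual volumes must not overlap: pairwise centre distance check
        for i, a in enumerate(self.lesion_specs):
            ra = a.diameter_mm / 2 + self.manual_margin_mm
            for b in self.lesion_specs[i + 1 :]:
                rb = b.diameter_mm / 2 + self.manual_margin_mm
                d = float(
                    np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
                )
                if d < ra + rb:
                    raise PlacementError(
                        f"manual volumes overlap for lesions at {a.center_mm} "
                        f"and {b.center_mm}"
                    )

    def _inside_body(self, x_mm: float, y_mm: float) -> bool:
        g = self.body_geometry
        return (
            abs(x_mm / g.semi_axis_x_mm) ** g.exponent
            + abs(y_mm / g.semi_axis_y_mm) ** g.exponent
        ) <= 1.0


@dataclass
class DigitalPatient:
    """Synthetic stand-in for one scanned patient."""

    patient_id: str
    hu_volume: np.ndarray  # float, HU
    tissue_labels: np.ndarray  # int codes, see LABEL_NAMES
    activity_truth: np.ndarray  # float, SUV units
    body_mask: np.ndarray  # bool
    manual_volumes: list[tuple[np.ndarray, str]]  # (bool mask, kind)
    voxel_spacing_mm: tuple[float, float, float]
    weight_kg: float
    injected_dose_MBq: float
    seed: int

    def validate(self) -> None:
        assert self.body_mask.dtype == bool
        if not np.array_equal(self.body_mask, self.tissue_labels != EXTERNAL_AIR):
            raise AssertionError("body_mask must equal (labels != external_air)")
        if np.any(self.activity_truth < 0):
            raise AssertionError("activity_truth must be non-negative")
        if np.any(self.activity_truth[~self.body_mask] != 0):
            raise AssertionError("activity_truth must vanish outside the body")


# --------------------------------------------------------------------------
# Default anatomy
# --------------------------------------------------------------------------


def default_bone_sites() -> tuple[BoneSite, ...]:
    """Two femoral-head surrogates and a sacrum surrogate (+y = posterior)."""
    return (
        BoneSite((-100.0, 10.0), 22.0, name="femoral_head_left"),
        BoneSite((100.0, 10.0), 22.0, name="femoral_head_right"),
        BoneSite((0.0, 62.0), 20.0, name="sacrum"),
    )


def default_spec() -> PhantomSpec:
    """The default pelvic phantom used by the study pipeline."""
    return PhantomSpec(
        bone_sites=default_bone_sites(),
        lesion_specs=(
            LesionSpec((0.0, 0.0, 0.0), 20.0, 8.0, "primary"),
            LesionSpec((55.0, -25.0, 0.0), 12.0, 6.0, "nodal"),
        ),
        air_pockets=(AirPocket((0.0, 35.0, 0.0), 10.0),),
    )


# --------------------------------------------------------------------------
# Patient generation
# --------------------------------------------------------------------------


def _grid_mm(spec: PhantomSpec):
    """Voxel-centre coordinates in mm, origin at the grid centre."""
    axes = []
    for n, d in zip(spec.grid_shape, spec.voxel_spacing_mm):
        axes.append((np.arange(n) - (n - 1) / 2.0) * d)
    return np.meshgrid(*axes, indexing="ij")


def generate_patient(
    spec: PhantomSpec, seed: int | None = None, patient_id: str = "p00"
) -> DigitalPatient:
    """Build one :class:`DigitalPatient` deterministically from (spec, seed)."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    xx, yy, zz = _grid_mm(spec)
    g = spec.body_geometry

    r_outer = (
        np.abs(xx / g.semi_axis_x_mm) ** g.exponent
        + np.abs(yy / g.semi_axis_y_mm) ** g.exponent
    )
    body = r_outer <= 1.0
    ax_in = max(g.semi_axis_x_mm - g.fat_thickness_mm, 1.0)
    ay_in = max(g.semi_axis_y_mm - g.fat_thickness_mm, 1.0)
    r_inner = (
        np.abs(xx / ax_in) ** g.exponent + np.abs(yy / ay_in) ** g.exponent
    )

    labels = np.full(spec.grid_shape, EXTERNAL_AIR, dtype=np.int16)
    labels[body] = SOFT_TISSUE
    labels[body & (r_inner > 1.0)] = FAT

    for b in spec.bone_sites:
        disc = (xx - b.center_mm[0]) ** 2 + (yy - b.center_mm[1]) ** 2 <= (
            b.radius_mm**2
        )
        labels[disc & body] = BONE

    for p in spec.air_pockets:
        ball = (
            (xx - p.center_mm[0]) ** 2
            + (yy - p.center_mm[1]) ** 2
            + (zz - p.center_mm[2]) ** 2
        ) <= p.radius_mm**2
        labels[ball & body] = AIR_POCKET

    body_mask = labels != EXTERNAL_AIR

    # HU: class means plus Gaussian texture inside the body.  Air stays exact.
    hu = np.full(spec.grid_shape, DEFAULT_HU[EXTERNAL_AIR], dtype=np.float64)
    for code, value in DEFAULT_HU.items():
        hu[labels == code] = value
    for b in spec.bone_sites:
        disc = (xx - b.center_mm[0]) ** 2 + (yy - b.center_mm[1]) ** 2 <= (
            b.radius_mm**2
        )
        hu[disc & (labels == BONE)] = b.hu_mean
    noise = rng.normal(0.0, 1.0, size=spec.grid_shape)
    tissue = (labels == FAT) | (labels == SOFT_TISSUE)
    hu[tissue] += spec.hu_noise_sd * noise[tissue]
    for b in spec.bone_sites:
        disc = (xx - b.center_mm[0]) ** 2 + (yy - b.center_mm[1]) ** 2 <= (
            b.radius_mm**2
        )
        sel = disc & (labels == BONE)
        hu[sel] += b.hu_spread * noise[sel]

    # Activity truth in SUV units
    activity = np.zeros(spec.grid_shape)
    activity[labels == SOFT_TISSUE] = spec.background_suv
    activity[labels == BONE] = spec.background_suv
    activity[labels == FAT] = spec.background_suv * spec.fat_uptake_fraction

    manual_volumes: list[tuple[np.ndarray, str]] = []
    for les in spec.lesion_specs:
        r = les.diameter_mm / 2.0
        dist = np.sqrt(
            (xx - les.center_mm[0]) ** 2
            + (yy - les.center_mm[1]) ** 2
            + (zz - les.center_mm[2]) ** 2
        )
        plateau = dist <= r
        if not np.all(body_mask[plateau]):
            raise PlacementError(
                f"lesion at {les.center_mm} extends outside the body"
            )
        # plateau + linear falloff to the local background
        f = np.clip((r + spec.lesion_falloff_mm - dist) / spec.lesion_falloff_mm, 0.0, 1.0)
        profile = activity + f * (les.peak_suv - activity)
        lesion_support = (f > 0) & body_mask & (labels != AIR_POCKET)
        activity[lesion_support] = np.maximum(
            activity[lesion_support], profile[lesion_support]
        )
        manual = (dist <= r + spec.manual_margin_mm) & body_mask
        manual_volumes.append((manual, les.kind))

    for i, (m_i, _) in enumerate(manual_volumes):
        for m_j, _ in manual_volumes[i + 1 :]:
            if np.any(m_i & m_j):
                raise PlacementError("manual volumes overlap on the voxel grid")

    patient = DigitalPatient(
        patient_id=patient_id,
        hu_volume=hu,
        tissue_labels=labels,
        activity_truth=activity,
        body_mask=body_mask,
        manual_volumes=manual_volumes,
        voxel_spacing_mm=spec.voxel_spacing_mm,
        weight_kg=spec.weight_kg,
        injected_dose_MBq=spec.injected_dose_MBq,
        seed=seed,
    )
    patient.validate()
    return patient


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def patient_subseeds(master_seed: int, index: int) -> tuple[int, int]:
    """Per-patient (jitter, volume) sub-seeds.

    Fixed rule: ``SeedSequence([master_seed, index])`` spawned into two
    children, each mapped to a 31-bit integer.  Any single patient is
    reproducible from (master_seed, index) alone, independent of cohort size.
    """
    children = np.random.SeedSequence([int(master_seed), int(index)]).spawn(2)
    return tuple(int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children)


def _jitter(rng: np.random.Generator, value: float, rel: float = 0.10) -> float:
    return float(value * (1.0 + rel * rng.uniform(-1.0, 1.0)))


def generate_cohort(
    spec_template: PhantomSpec,
    n_patients: int,
    n_primary: int,
    n_nodal: int,
    seed: int,
) -> list[DigitalPatient]:
    """Generate a cohort with exactly ``n_primary`` primary and ``n_nodal``
    nodal lesions distributed one per patient (cycling if counts exceed the
    cohort size).  Per-patient anatomy is a seeded ±10% jitter of the
    template's body axes, bone radii and lesion SUV/diameter.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    protos = {les.kind: les for les in spec_template.lesion_specs}
    for kind, n in (("primary", n_primary), ("nodal", n_nodal)):
        if n > 0 and kind not in protos:
            raise ValueError(f"template provides no {kind} lesion prototype")

    patients = []
    for i in range(n_patients):
        jitter_seed, vol_seed = patient_subseeds(seed, i)
        rng = np.random.default_rng(jitter_seed)
        g = spec_template.body_geometry
        body = replace(
            g,
            semi_axis_x_mm=_jitter(rng, g.semi_axis_x_mm),
            semi_axis_y_mm=_jitter(rng, g.semi_axis_y_mm),
        )
        bones = tuple(
            replace(b, radius_mm=_jitter(rng, b.radius_mm))
            for b in spec_template.bone_sites
        )
        lesions = []
        for kind, n_kind in (("primary", n_primary), ("nodal", n_nodal)):
            n_here = sum(1 for j in range(n_kind) if j % n_patients == i)
            for _ in range(n_here):
                p = protos[kind]
                lesions.append(
                    replace(
                        p,
                        diameter_mm=_jitter(rng, p.diameter_mm),
                        peak_suv=_jitter(rng, p.peak_suv),
                    )
                )
        spec_i = replace(
            spec_template,
            body_geometry=body,
            bone_sites=bones,
            lesion_specs=tuple(lesions),
            seed=vol_seed,
        )
        patients.append(
            generate_patient(spec_i, vol_seed, patient_id=f"p{i:02d}")
        )

    got_primary = sum(
        sum(1 for _, k in p.manual_volumes if k == "primary") for p in patients
    )
    got_nodal = sum(
        sum(1 for _, k in p.manual_volumes if k == "nodal") for p in patients
    )
    assert got_primary == n_primary and got_nodal == n_nodal
    return patients


# --------------------------------------------------------------------------
# Controlled degradations
# --------------------------------------------------------------------------


def degrade_to_mrac_labels(patient: DigitalPatient) -> np.ndarray:
    """Collapse the CT tissue classes to the Dixon-style MRAC classes.

    Bone becomes soft tissue (the pelvic MRAC failure mode) and internal air
    pockets become a water-equivalent soft-tissue surrogate; external air is
    preserved.  Pure per-voxel relabelling.
    """
    mapping = {
        EXTERNAL_AIR: MR_AIR,
        FAT: MR_FAT,
        SOFT_TISSUE: MR_SOFT_TISSUE,
        BONE: MR_SOFT_TISSUE,
        AIR_POCKET: MR_SOFT_TISSUE,
    }
    lut = np.zeros(max(mapping) + 1, dtype=np.int16)
    for src, dst in mapping.items():
        lut[src] = dst
    return lut[patient.tissue_labels]


def make_sct_hu(
    patient: DigitalPatient,
    bone_hu_bias: float = 0.0,
    bone_boundary_shift_mm: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic-CT-style HU volume: ground truth plus controlled bone errors.

    ``bone_hu_bias`` is added to every bone voxel; a positive
    ``bone_boundary_shift_mm`` grows the bone region morphologically (new
    voxels receive the mean bone HU), a negative one shrinks it (removed
    voxels receive soft-tissue HU).  With (0, 0) the input is returned
    unchanged.  Shifts larger than the largest bone inradius are clamped with
    a warning.
    """
    hu = patient.hu_volume.copy()
    bone = patient.tissue_labels == BONE
    if not np.any(bone):
        return hu
    rng = np.random.default_rng(seed)
    spacing = patient.voxel_spacing_mm

    shift = float(bone_boundary_shift_mm)
    if shift != 0.0:
        inradius = float(
            ndimage.distance_transform_edt(bone, sampling=spacing).max()
        )
        if abs(shift) > inradius:
            warnings.warn(
                f"bone boundary shift {shift} mm exceeds the largest bone "
                f"inradius {inradius:.1f} mm; clamping",
                stacklevel=2,
            )
            shift = float(np.sign(shift) * inradius)
        mean_bone_hu = float(hu[bone].mean())
        if shift > 0:
            dist_out = ndimage.distance_transform_edt(~bone, sampling=spacing)
            grown = (~bone) & (dist_out <= shift) & patient.body_mask
            hu[grown] = mean_bone_hu + rng.normal(0, patient_hu_sd(patient), grown.sum())
            bone = bone | grown
        else:
            dist_in = ndimage.distance_transform_edt(bone, sampling=spacing)
            shrunk = bone & (dist_in <= -shift)
            hu[shrunk] = DEFAULT_HU[SOFT_TISSUE] + rng.normal(
                0, patient_hu_sd(patient), shrunk.sum()
            )
            bone = bone & ~shrunk

    if bone_hu_bias != 0.0:
        hu[bone] += float(bone_hu_bias)
    return hu


def patient_hu_sd(patient: DigitalPatient) -> float:
    """HU texture level for synthetic-CT infill, estimated from soft tissue."""
    soft = patient.tissue_labels == SOFT_TISSUE
    if not np.any(soft):
        return 0.0
    return float(patient.hu_volume[soft].std())


# --------------------------------------------------------------------------
# NIfTI / JSON persistence
# --------------------------------------------------------------------------


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_patient(patient: DigitalPatient, out_dir: str | Path) -> Path:
    """Write one patient as NIfTI volumes plus a JSON metadata sidecar."""
    out = Path(out_dir) / patient.patient_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(patient.voxel_spacing_mm)

    def _save(name: str, arr: np.ndarray, dtype) -> None:
        nib.save(nib.Nifti1Image(arr.astype(dtype), aff), out / f"{name}.nii")

    _save("hu", patient.hu_volume, np.float32)
    _save("labels", patient.tissue_labels, np.int16)
    _save("activity", patient.activity_truth, np.float32)
    _save("body_mask", patient.body_mask, np.uint8)
    for i, (mask, kind) in enumerate(patient.manual_volumes):
        _save(f"manual_{i:02d}_{kind}", mask, np.uint8)
    meta = {
        "patient_id": patient.patient_id,
        "weight_kg": patient.weight_kg,
        "injected_dose_MBq": patient.injected_dose_MBq,
        "seed": patient.seed,
        "voxel_spacing_mm": list(patient.voxel_spacing_mm),
        "manual_volume_kinds": [k for _, k in patient.manual_volumes],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_patient(patient_dir: str | Path) -> DigitalPatient:
    """Inverse of :func:`save_patient`."""
    d = Path(patient_dir)
    meta = json.loads((d / "meta.json").read_text())

    def _load(name: str) -> np.ndarray:
        return np.asarray(nib.load(d / f"{name}.nii").dataobj)

    manual = [
        (_load(f"manual_{i:02d}_{kind}").astype(bool), kind)
        for i, kind in enumerate(meta["manual_volume_kinds"])
    ]
    return DigitalPatient(
        patient_id=meta["patient_id"],
        hu_volume=_load("hu").astype(np.float64),
        tissue_labels=_load("labels").astype(np.int16),
        activity_truth=_load("activity").astype(np.float64),
        body_mask=_load("body_mask").astype(bool),
        manual_volumes=manual,
        voxel_spacing_mm=tuple(meta["voxel_spacing_mm"]),
        weight_kg=meta["weight_kg"],
        injected_dose_MBq=meta["injected_dose_MBq"],
        seed=meta["seed"],
    )
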