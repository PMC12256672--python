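"""Domain types for radiotherapy objects and DICOM-RT file I/O.

All geometry lives in the DICOM patient coordinate system, in mm.  A
:class:`Grid3D` describes a regular axial grid: ``origin`` is the patient
coordinate ``(x, y, z)`` of the *center* of voxel ``(0, 0, 0)``, ``spacing``
is ``(dx, dy, dz)``, and ``shape`` is ``(nx, ny, nz)``.  Scalar arrays
attached to a grid (CT numbers, dose) are indexed ``[iz, iy, ix]`` — the
natural DICOM frame/row/column order — so ``values.shape == (nz, ny, nx)``.

Only axial series with identity direction cosines are supported; oblique
series are rejected with :class:`OrientationError`.  Dose is held as float
Gy internally; the stored-integer + scaling representation of RT Dose
objects is purely an I/O concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTPlanStorage,
    RTStructureSetStorage,
)

#: UID root for all UIDs minted by this package.
UID_ROOT = "1.2.826.0.1.3680043.10.1157."

#: Private creator string used for fields DICOM has no public tag for
#: (delivered fractions, plan-to-plan links by label).
PRIVATE_CREATOR = "RTCOHORT"
PRIVATE_GROUP = 0x3261

#: Upper sanity bound on delivered fractions (no thoracic course exceeds this).
MAX_DELIVERED_FRACTIONS = 200

_IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class RTModelError(Exception):
    """Base class for radiotherapy-model errors."""


class ModalityError(RTModelError):
    """A required DICOM modality is missing or duplicated."""

    def __init__(self, modality: str, problem: str):
        self.modality = modality
        self.problem = problem
        super().__init__(f"{problem} modality: {modality}")


class OrientationError(RTModelError):
    """Series is not axial with identity direction cosines."""


class ValidationError(RTModelError):
    """An object violates one of its invariants."""


class SliceSpacingError(RTModelError):
    """CT slice positions are not uniformly spaced within tolerance."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid3D:
    """Regular axial voxel grid in patient coordinates.

    Attributes
    ----------
    origin : tuple of float
        ``(x, y, z)`` mm of the center of voxel ``(0, 0, 0)``.
    spacing : tuple of float
        ``(dx, dy, dz)`` mm; all components strictly positive.
    shape : tuple of int
        ``(nx, ny, nz)``; note attached value arrays are ``(nz, ny, nx)``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValidationError(f"grid shape must be positive, got {self.shape}")

    @property
    def array_shape(self) -> tuple[int, int, int]:
        """Shape ``(nz, ny, nx)`` of value arrays living on this grid."""
        nx, ny, nz = self.shape
        return (nz, ny, nx)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[0])

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])

    @property
    def z_centers(self) -> np.ndarray:
        return self.origin[2] + self.spacing[2] * np.arange(self.shape[2])

    def z_index(self, z: float, tol_factor: float = 0.5) -> int:
        """Index of the grid plane matching ``z`` within ``tol_factor * dz``.

        Raises :class:`ValidationError` when no plane is close enough.
        """
        dz = self.spacing[2]
        iz = int(round((z - self.origin[2]) / dz))
        if iz < 0 or iz >= self.shape[2] or abs(z - self.z_centers[iz]) > tol_factor * dz + 1e-9:
            raise ValidationError(f"no grid plane within {tol_factor} * dz of z={z:.3f} mm")
        return iz

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """Patient-coordinate ``(x, y, z)`` centers of True voxels of a
        ``(nz, ny, nx)`` boolean array, ordered by flat index."""
        iz, iy, ix = np.nonzero(mask)
        return np.column_stack(
            [
                self.origin[0] + self.spacing[0] * ix,
                self.origin[1] + self.spacing[1] * iy,
                self.origin[2] + self.spacing[2] * iz,
            ]
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])


@dataclass
class CTImageSeries:
    """A CT image series on a regular axial grid, values in HU."""

    series_id: str
    grid: Grid3D
    values: np.ndarray  # int16, shape (nz, ny, nx)

    def validate(self) -> None:
        if tuple(self.values.shape) != self.grid.array_shape:
            raise ValidationError(
                f"CT values shape {self.values.shape} != grid {self.grid.array_shape}"
            )


Polygon = np.ndarray  # (n_vertices, 2) float array of in-plane (x, y) mm


@dataclass
class Structure:
    """A named delineation: closed planar polygons per axial slice.

    ``slices`` maps a z position (mm) to the list of closed polygons on
    that plane; the first vertex is implicitly joined to the last.
    ``interpretation`` is one of ``"organ"``, ``"reference"``, ``"other"``.
    """

    name: str
    slices: list[tuple[float, list[Polygon]]]
    interpretation: str = "organ"

    def validate(self) -> None:
        if self.interpretation not in ("organ", "reference", "other"):
            raise ValidationError(f"bad interpretation {self.interpretation!r}")
        for z, polys in self.slices:
            for poly in polys:
                poly = np.asarray(poly)
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise ValidationError(
                        f"structure {self.name!r}: polygon at z={z} needs >= 3 (x, y) vertices"
                    )

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "Structure":
        return Structure(
            self.name,
            [(z + dz, [np.asarray(p, float) + [dx, dy] for p in polys]) for z, polys in self.slices],
            self.interpretation,
        )


@dataclass
class StructureSet:
    structures: list[Structure]
    frame_of_reference: str = ""
    approval_status: str = "approved"  # approved | unapproved
    label: str = "StructureSet"

    def validate(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate structure names in set: {sorted(names)}")
        for s in self.structures:
            s.validate()

    def find(self, name: str) -> Structure | None:
        for s in self.structures:
            if s.name == name:
                return s
        return None


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a regular axial grid."""

    grid: Grid3D
    values: np.ndarray  # float, shape (nz, ny, nx)

    def validate(self) -> None:
        if tuple(self.values.shape) != self.grid.array_shape:
            raise ValidationError(
                f"dose values shape {self.values.shape} != grid {self.grid.array_shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError("dose values must be >= 0")


@dataclass
class TreatmentPlanRecord:
    plan_id: str
    prescribed_dose: float  # Gy
    planned_fractions: int
    delivered_fractions: int
    approval_status: str = "approved"
    linked_plan_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.plan_id:
            raise ValidationError("plan_id must be non-empty")
        if self.planned_fractions < 1:
            raise ValidationError("planned_fractions must be >= 1")
        if not 0 <= self.delivered_fractions <= MAX_DELIVERED_FRACTIONS:
            raise ValidationError(
                f"delivered_fractions {self.delivered_fractions} outside [0, {MAX_DELIVERED_FRACTIONS}]"
            )


#: label used for machine-generated structure sets
AUTOSEG_LABEL = "autoseg"


@dataclass
class RTCase:
    """One patient case: a CT series plus any RT objects that exist.

    ``doses`` is keyed by the plan_id the dose belongs to (or the dose's
    own identifier when the plan link cannot be resolved).  A case may
    carry several structure sets distinguished by label — typically the
    manual one plus an ``"autoseg"`` set; :attr:`structure_set` is the
    first non-autoseg set.
    """

    patient_id: str
    ct: CTImageSeries
    structure_sets: list[StructureSet] = field(default_factory=list)
    plans: list[TreatmentPlanRecord] = field(default_factory=list)
    doses: dict[str, DoseGrid] = field(default_factory=dict)

    @property
    def structure_set(self) -> StructureSet | None:
        for ss in self.structure_sets:
            if ss.label != AUTOSEG_LABEL:
                return ss
        return None

    def get_structure_set(self, label: str) -> StructureSet | None:
        for ss in self.structure_sets:
            if ss.label == label:
                return ss
        return None

    @property
    def plan(self) -> TreatmentPlanRecord:
        """The single plan of a one-plan case."""
        if len(self.plans) != 1:
            raise ModalityError("RTPLAN", f"expected exactly 1, found {len(self.plans)}")
        return self.plans[0]

    @property
    def dose(self) -> DoseGrid:
        if len(self.doses) != 1:
            raise ModalityError("RTDOSE", f"expected exactly 1, found {len(self.doses)}")
        return next(iter(self.doses.values()))

    def validate(self) -> None:
        self.ct.validate()
        labels = [ss.label for ss in self.structure_sets]
        if len(labels) != len(set(labels)):
            raise ValidationError(f"duplicate structure set labels: {labels}")
        for ss in self.structure_sets:
            ss.validate()
        for p in self.plans:
            p.validate()
        for d in self.doses.values():
            d.validate()


# --------------------------------------------------------------------------
# deterministic UIDs
# --------------------------------------------------------------------------


def make_uid(*parts: str) -> str:
    """Deterministic DICOM UID under the package root, from text parts."""
    import hashlib

    h = hashlib.blake2b("\x1f".join(parts).encode(), digest_size=16).digest()
    # 29 decimal digits starting with 1 -> valid component, total < 64 chars
    return UID_ROOT + str(10**28 + int.from_bytes(h, "big") % 10**28)


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------


def _file_meta(sop_class_uid: str, sop_instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = UID_ROOT + "1"
    return meta


def _base_dataset(case_id: str, modality: str, sop_class_uid: str, sop_instance_uid: str) -> pydicom.FileDataset:
    ds = pydicom.FileDataset(
        None, Dataset(), file_meta=_file_meta(sop_class_uid, sop_instance_uid), preamble=b"\x00" * 128
    )
    ds.PatientName = case_id
    ds.PatientID = case_id
    ds.Modality = modality
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = sop_instance_uid
    ds.StudyInstanceUID = make_uid(case_id, "study")
    ds.StudyID = "1"
    return ds


def _write(ds: pydicom.FileDataset, path: Path) -> Path:
    ds.save_as(path, enforce_file_format=True)
    return path


def _approval(status: str) -> str:
    return "APPROVED" if status == "approved" else "UNAPPROVED"


_INTERP_TO_DICOM = {"organ": "ORGAN", "reference": "EXTERNAL", "other": ""}
_DICOM_TO_INTERP = {"ORGAN": "organ", "EXTERNAL": "reference"}


def write_case(case: RTCase, directory: str | Path) -> list[Path]:
    """Write a case as standard DICOM files under ``directory``.

    One CT Image Storage file per slice (``ct_####.dcm``), one RT Structure
    Set (``rs.dcm``), and one RT Dose / RT Plan pair per plan
    (``rd_<n>.dcm`` / ``rp_<n>.dcm``).  Returns the written paths.  Objects
    are validated first; invariant violations raise
    :class:`ValidationError` and nothing is written.
    """
    case.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    pid = case.patient_id

    frame_uid = make_uid(pid, "frame")
    ct = case.ct
    nx, ny, nz = ct.grid.shape
    series_uid = make_uid(pid, "ct-series", ct.series_id)
    hu = np.asarray(ct.values)
    stored = np.clip(hu.astype(np.int32) + 1024, 0, 65535).astype(np.uint16)
    for iz in range(nz):
        sop_uid = make_uid(pid, "ct", ct.series_id, str(iz))
        ds = _base_dataset(pid, "CT", CTImageStorage, sop_uid)
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = iz + 1
        ds.FrameOfReferenceUID = frame_uid
        ds.ImageOrientationPatient = list(_IDENTITY_ORIENTATION)
        ds.ImagePositionPatient = [
            f"{ct.grid.origin[0]:.6f}",
            f"{ct.grid.origin[1]:.6f}",
            f"{ct.grid.z_centers[iz]:.6f}",
        ]
        ds.PixelSpacing = [f"{ct.grid.spacing[1]:.6f}", f"{ct.grid.spacing[0]:.6f}"]
        ds.SliceThickness = f"{ct.grid.spacing[2]:.6f}"
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = "-1024"
        ds.RescaleSlope = "1"
        ds.PixelData = stored[iz].tobytes()
        written.append(_write(ds, directory / f"ct_{iz:04d}.dcm"))

    for i, ss in enumerate(case.structure_sets):
        written.append(
            _write_structure_set(ss, pid, frame_uid, series_uid, directory / f"rs_{i}.dcm")
        )

    for k, plan in enumerate(case.plans):
        plan_sop = make_uid(pid, "plan", plan.plan_id)
        ds = _base_dataset(pid, "RTPLAN", RTPlanStorage, plan_sop)
        ds.SeriesInstanceUID = make_uid(pid, "plan-series", plan.plan_id)
        ds.SeriesNumber = 10 + k
        ds.FrameOfReferenceUID = frame_uid
        ds.RTPlanLabel = plan.plan_id
        ds.RTPlanGeometry = "PATIENT"
        ds.ApprovalStatus = _approval(plan.approval_status)
        fg = Dataset()
        fg.FractionGroupNumber = 1
        fg.NumberOfFractionsPlanned = plan.planned_fractions
        ds.FractionGroupSequence = Sequence([fg])
        dr = Dataset()
        dr.DoseReferenceNumber = 1
        dr.DoseReferenceStructureType = "SITE"
        dr.DoseReferenceType = "TARGET"
        dr.TargetPrescriptionDose = f"{plan.prescribed_dose:.6f}"
        ds.DoseReferenceSequence = Sequence([dr])
        block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR, create=True)
        block.add_new(0x01, "IS", str(plan.delivered_fractions))
        if plan.linked_plan_ids:
            block.add_new(0x02, "LO", list(plan.linked_plan_ids))
        written.append(_write(ds, directory / f"rp_{k}.dcm"))

        dose = case.doses.get(plan.plan_id)
        if dose is not None:
            written.append(
                _write_dose(dose, pid, plan.plan_id, plan_sop, frame_uid, k, directory / f"rd_{k}.dcm")
            )

    # doses whose plan is not in the case (kept readable, flagged downstream)
    plan_ids = {p.plan_id for p in case.plans}
    for j, (key, dose) in enumerate(sorted(case.doses.items())):
        if key not in plan_ids:
            written.append(
                _write_dose(dose, pid, key, None, frame_uid, 90 + j, directory / f"rd_x{j}.dcm")
            )
    return written


def _write_structure_set(
    ss: StructureSet, pid: str, frame_uid: str, ct_series_uid: str, path: Path
) -> Path:
    sop_uid = make_uid(pid, "rtstruct", ss.label, *(s.name for s in ss.structures))
    ds = _base_dataset(pid, "RTSTRUCT", RTStructureSetStorage, sop_uid)
    ds.SeriesInstanceUID = make_uid(pid, "rtstruct-series", ss.label)
    ds.SeriesNumber = 2
    ds.StructureSetLabel = ss.label
    ds.ApprovalStatus = _approval(ss.approval_status)

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = ss.frame_of_reference or frame_uid
    ds.ReferencedFrameOfReferenceSequence = Sequence([ref_frame])

    rois, contours, observations = [], [], []
    for i, s in enumerate(ss.structures, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ReferencedFrameOfReferenceUID = ref_frame.FrameOfReferenceUID
        roi.ROIName = s.name
        roi.ROIGenerationAlgorithm = "MANUAL"
        rois.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        items = []
        for z, polys in s.slices:
            for poly in polys:
                poly = np.asarray(poly, float)
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = poly.shape[0]
                data = np.column_stack([poly, np.full(poly.shape[0], z)]).ravel()
                c.ContourData = [f"{v:.6f}" for v in data]
                items.append(c)
        rc.ContourSequence = Sequence(items)
        contours.append(rc)

        ob = Dataset()
        ob.ObservationNumber = i
        ob.ReferencedROINumber = i
        ob.RTROIInterpretedType = _INTERP_TO_DICOM[s.interpretation]
        ob.ROIInterpreter = ""
        observations.append(ob)

    ds.StructureSetROISequence = Sequence(rois)
    ds.ROIContourSequence = Sequence(contours)
    ds.RTROIObservationsSequence = Sequence(observations)
    return _write(ds, path)


def _write_dose(
    dose: DoseGrid,
    pid: str,
    plan_key: str,
    plan_sop: str | None,
    frame_uid: str,
    series_no: int,
    path: Path,
) -> Path:
    nx, ny, nz = dose.grid.shape
    sop_uid = make_uid(pid, "dose", plan_key)
    ds = _base_dataset(pid, "RTDOSE", RTDoseStorage, sop_uid)
    ds.SeriesInstanceUID = make_uid(pid, "dose-series", plan_key)
    ds.SeriesNumber = series_no
    ds.FrameOfReferenceUID = frame_uid
    ds.ImageOrientationPatient = list(_IDENTITY_ORIENTATION)
    ds.ImagePositionPatient = [
        f"{dose.grid.origin[0]:.6f}",
        f"{dose.grid.origin[1]:.6f}",
        f"{dose.grid.origin[2]:.6f}",
    ]
    ds.PixelSpacing = [f"{dose.grid.spacing[1]:.6f}", f"{dose.grid.spacing[0]:.6f}"]
    ds.SliceThickness = f"{dose.grid.spacing[2]:.6f}"
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [f"{dose.grid.spacing[2] * i:.6f}" for i in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    vmax = float(np.max(dose.values))
    scaling = vmax / (2**31) if vmax > 0 else 1.0
    ds.DoseGridScaling = f"{scaling:.10e}"
    stored = np.round(np.asarray(dose.values, float) / scaling).astype(np.uint32)
    ds.PixelData = stored.tobytes()
    if plan_sop is not None:
        ref = Dataset()
        ref.ReferencedSOPClassUID = RTPlanStorage
        ref.ReferencedSOPInstanceUID = plan_sop
        ds.ReferencedRTPlanSequence = Sequence([ref])
    return _write(ds, path)


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------


def iter_dicom_files(directory: str | Path) -> Iterator[Path]:
    yield from sorted(Path(directory).glob("*.dcm"))


def _check_orientation(ds: Dataset) -> None:
    iop = tuple(float(v) for v in ds.ImageOrientationPatient)
    if not all(math.isclose(a, b, abs_tol=1e-6) for a, b in zip(iop, _IDENTITY_ORIENTATION)):
        raise OrientationError(f"only axial identity orientation supported, got {iop}")


def read_case(directory: str | Path, spacing_rel_tol: float = 1e-3) -> RTCase:
    """Read one patient case from a directory of DICOM files.

    The directory must hold exactly one CT series; RT structure set, dose
    and plan objects are optional (their absence is a QC finding, not a
    read error).  Two RT Dose objects referencing the same plan raise
    :class:`ModalityError`; non-uniform CT slice spacing beyond
    ``spacing_rel_tol`` raises :class:`SliceSpacingError`.
    """
    directory = Path(directory)
    ct_slices: list[Dataset] = []
    structs: list[Dataset] = []
    plans: list[Dataset] = []
    doses: list[Dataset] = []
    for path in iter_dicom_files(directory):
        ds = pydicom.dcmread(path)
        modality = getattr(ds, "Modality", "")
        if modality == "CT":
            ct_slices.append(ds)
        elif modality == "RTSTRUCT":
            structs.append(ds)
        elif modality == "RTPLAN":
            plans.append(ds)
        elif modality == "RTDOSE":
            doses.append(ds)

    if not ct_slices:
        raise ModalityError("CT", "missing")
    series_ids = {ds.SeriesInstanceUID for ds in ct_slices}
    if len(series_ids) > 1:
        raise ModalityError("CT", "duplicate")
    ct = _read_ct(ct_slices, spacing_rel_tol)
    patient_id = str(ct_slices[0].PatientID)

    structure_sets = [_read_structure_set(ds) for ds in structs]
    labels = [ss.label for ss in structure_sets]
    if len(labels) != len(set(labels)):
        raise ModalityError("RTSTRUCT", "duplicate")

    plan_records: list[TreatmentPlanRecord] = []
    plan_sop_to_id: dict[str, str] = {}
    for ds in plans:
        rec = _read_plan(ds)
        plan_records.append(rec)
        plan_sop_to_id[str(ds.SOPInstanceUID)] = rec.plan_id

    dose_map: dict[str, DoseGrid] = {}
    for ds in doses:
        key = str(ds.SOPInstanceUID)
        refs = getattr(ds, "ReferencedRTPlanSequence", None)
        if refs:
            ref_uid = str(refs[0].ReferencedSOPInstanceUID)
            key = plan_sop_to_id.get(ref_uid, key)
        if key in dose_map:
            raise ModalityError("RTDOSE", "duplicate")
        dose_map[key] = _read_dose(ds)

    return RTCase(
        patient_id=patient_id,
        ct=ct,
        structure_sets=structure_sets,
        plans=plan_records,
        doses=dose_map,
    )


def _read_ct(slices: list[Dataset], spacing_rel_tol: float) -> CTImageSeries:
    _check_orientation(slices[0])
    slices = sorted(slices, key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        steps = np.diff(zs)
        if np.any(steps <= 0):
            raise SliceSpacingError("slice z positions not strictly increasing")
        dz = float(np.mean(steps))
        if np.max(np.abs(steps - dz)) > spacing_rel_tol * dz:
            raise SliceSpacingError(f"non-uniform slice spacing: steps {steps}")
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    x0, y0 = float(first.ImagePositionPatient[0]), float(first.ImagePositionPatient[1])
    grid = Grid3D(
        origin=(x0, y0, float(zs[0])),
        spacing=(dx, dy, dz),
        shape=(int(first.Columns), int(first.Rows), len(slices)),
    )
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    vol = np.stack([ds.pixel_array for ds in slices]).astype(np.float64) * slope + intercept
    return CTImageSeries(
        series_id=str(first.SeriesInstanceUID),
        grid=grid,
        values=np.round(vol).astype(np.int16),
    )


def _read_structure_set(ds: Dataset) -> StructureSet:
    roi_names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    interps = {
        int(o.ReferencedROINumber): _DICOM_TO_INTERP.get(str(getattr(o, "RTROIInterpretedType", "")), "other")
        for o in getattr(ds, "RTROIObservationsSequence", [])
    }
    structures = []
    for rc in getattr(ds, "ROIContourSequence", []):
        n = int(rc.ReferencedROINumber)
        by_z: dict[float, list[Polygon]] = {}
        for c in getattr(rc, "ContourSequence", []):
            pts = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(np.round(pts[0, 2], 6))
            by_z.setdefault(z, []).append(pts[:, :2])
        structures.append(
            Structure(
                name=roi_names[n],
                slices=[(z, by_z[z]) for z in sorted(by_z)],
                interpretation=interps.get(n, "other"),
            )
        )
    frame = ""
    if getattr(ds, "ReferencedFrameOfReferenceSequence", None):
        frame = str(ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID)
    status = "approved" if str(getattr(ds, "ApprovalStatus", "APPROVED")) == "APPROVED" else "unapproved"
    return StructureSet(
        structures=structures,
        frame_of_reference=frame,
        approval_status=status,
        label=str(getattr(ds, "StructureSetLabel", "StructureSet")),
    )


def _read_plan(ds: Dataset) -> TreatmentPlanRecord:
    prescribed = 0.0
    if getattr(ds, "DoseReferenceSequence", None):
        prescribed = float(getattr(ds.DoseReferenceSequence[0], "TargetPrescriptionDose", 0.0))
    planned = 1
    if getattr(ds, "FractionGroupSequence", None):
        planned = int(ds.FractionGroupSequence[0].NumberOfFractionsPlanned)
    delivered = planned
    linked: list[str] = []
    try:
        block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR)
        delivered = int(block[0x01].value)
        if 0x02 in block:
            v = block[0x02].value
            linked = [str(v)] if isinstance(v, str) else [str(x) for x in v]
    except KeyError:
        pass
    status = "approved" if str(getattr(ds, "ApprovalStatus", "APPROVED")) == "APPROVED" else "unapproved"
    return TreatmentPlanRecord(
        plan_id=str(ds.RTPlanLabel),
        prescribed_dose=prescribed,
        planned_fractions=planned,
        delivered_fractions=delivered,
        approval_status=status,
        linked_plan_ids=linked,
    )


def _read_dose(ds: Dataset) -> DoseGrid:
    _check_orientation(ds)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else float(getattr(ds, "SliceThickness", 1.0))
    origin = (
        float(ds.ImagePositionPatient[0]),
        float(ds.ImagePositionPatient[1]),
        float(ds.ImagePositionPatient[2]) + float(offsets[0]),
    )
    grid = Grid3D(origin=origin, spacing=(dx, dy, dz), shape=(int(ds.Columns), int(ds.Rows), int(ds.NumberOfFrames)))
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(np.float64) * scaling
    return DoseGrid(grid=grid, values=values.reshape(grid.array_shape))


def rescaled(plan: TreatmentPlanRecord, **changes) -> TreatmentPlanRecord:
    """Copy of a plan record with fields replaced."""
    return replace(plan, **changes)
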