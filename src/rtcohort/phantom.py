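"""Synthetic thoracic DICOM-RT phantoms, cohorts, and error injection.

Each phantom case is a fully self-contained DICOM-RT patient: an axial
CT of a cylindrical "body" with two lung-like ellipsoids, three organs at
risk — a proximal-bronchial-tree-like branched air tube, a heart-like
ellipsoid, and an esophagus-like curved posterior tube — a BODY
reference structure, a dose grid, and a treatment plan with fraction
counts.  Organs carry distinct CT numbers so a simple threshold-based
autosegmentation backend can find them; realistic CT texture and
anatomical fidelity are non-goals — the geometry merely has to stress
the same code paths (thin branched surfaces, per-sex volume spread) as
real thoracic cases.

Everything is deterministic: the geometry is a pure function of the
:class:`PhantomSpec`, and cohort sampling is driven entirely by the
generator seed, so identical inputs give byte-identical DICOM files.

Cohorts are drawn with per-organ, per-sex normal volume distributions.
Clean (un-injected) patients are sampled from the central +/- 2.5 SD of
each distribution so that every quality-control outcome on a generated
cohort is decided by the error-injection ledger alone; ``volume_outlier``
injections place an organ volume at a stated number of SDs from its
stratum mean.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
import shapely.geometry

from rtcohort import rt_model
from rtcohort.cohort_setup import COHORT_LIST_COLUMNS
from rtcohort.curation import EXTRACTION_LOCKS_FILE, NomenclatureMap
from rtcohort.rt_model import (
    CTImageSeries,
    DoseGrid,
    Grid3D,
    RTCase,
    Structure,
    StructureSet,
    TreatmentPlanRecord,
    ValidationError,
    make_uid,
)

# standard organ names (the cleanup target nomenclature)
PBT_NAME = "Bronchus_Prox"
HEART_NAME = "Heart"
ESO_NAME = "Esophagus"
BODY_NAME = "BODY"
ORGAN_NAMES = (PBT_NAME, HEART_NAME, ESO_NAME)

# clinical-style aliases cycled through generated cohorts
ORGAN_ALIASES = {
    PBT_NAME: ["PBT", "Bronchial_Tree", "prox bronch"],
    HEART_NAME: ["HEART", "Hjarta", "Cor"],
    ESO_NAME: ["Oesophagus", "Esophagus_L", "ESO"],
}

# HU palette: organs are separable by thresholding
HU_AIR = -1000
HU_BODY = 40
HU_LUNG = -700
HU_HEART = 70
HU_ESO = 25

#: per-(organ, sex) volume distributions (mean, SD) in cm^3 used for cohorts
DEFAULT_POPULATION = {
    (HEART_NAME, "M"): (800.0, 80.0),
    (HEART_NAME, "F"): (650.0, 65.0),
    (ESO_NAME, "M"): (40.0, 6.0),
    (ESO_NAME, "F"): (34.0, 5.0),
    (PBT_NAME, "M"): (45.0, 7.0),
    (PBT_NAME, "F"): (38.0, 6.0),
}

#: clean cohort volumes stay within this many SDs of the stratum mean
CLEAN_TRUNCATION_SD = 2.5

_N_VERTICES = 48  # polygon resolution for generated contours


@dataclass
class PhantomSpec:
    """Full description of one synthetic thoracic case.

    Organ target volumes are in cm^3; ``None`` keeps the base geometry.
    ``dose_model`` is one of ``{"kind": "uniform", "dose": Gy}``,
    ``{"kind": "gradient", "gradient": Gy/mm, "axis": "x"|"y"|"z"}``
    (prescribed dose at the grid center, clipped at zero), or
    ``{"kind": "target", "center": (x, y, z), "radius": mm,
    "falloff": mm}`` (prescribed dose inside the sphere, Gaussian tail).
    """

    patient_id: str = "PT0001"
    sex: str = "M"
    course_id: str = "C1"
    plan_id: str = "ThorPlan1"
    prescribed_dose: float = 66.0
    planned_fractions: int = 33
    delivered_fractions: int = 33
    shape: tuple[int, int, int] = (96, 96, 64)  # (nx, ny, nz)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_radius: float = 100.0
    heart_volume: float | None = None
    eso_volume: float | None = None
    pbt_volume: float | None = None
    dose_model: dict = field(default_factory=lambda: {"kind": "uniform", "dose": 66.0})
    organ_names: dict = field(default_factory=lambda: {n: n for n in ORGAN_NAMES})
    extra_plan: bool = False  # add a second small plan (for multi-plan cases)

    def grid(self) -> Grid3D:
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        origin = (-dx * (nx - 1) / 2.0, -dy * (ny - 1) / 2.0, dz / 2.0)
        return Grid3D(origin=origin, spacing=self.spacing, shape=self.shape)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

_HEART_CENTER = (-10.0, -25.0, 62.0)
_HEART_SEMIAXES = (57.0, 52.0, 55.0)
_LUNG_CENTERS = ((68.0, -8.0, 85.0), (-68.0, -8.0, 85.0))
_LUNG_SEMIAXES = (28.0, 55.0, 68.0)
_PBT_XY = (0.0, -20.0)  # trachea axis
_TRACHEA_RADIUS = 10.0
_BRANCH_RADIUS = 8.0
_CARINA_Z = 100.0
_BRANCH_Z_MIN = 60.0
_BRANCH_OFFSET = 12.0  # keeps scaled-up branches disjoint (even-odd rule)
_BRANCH_SLOPE = 0.8
_ESO_Y = 45.0
_ESO_AMP = 6.0
_ESO_RADIUS = 8.5
_ESO_Z = (10.0, 150.0)


def _circle(cx: float, cy: float, r: float, n: int = _N_VERTICES) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _ellipse(cx: float, cy: float, rx: float, ry: float, n: int = _N_VERTICES) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _eso_center_x(z: np.ndarray | float) -> np.ndarray | float:
    z0, z1 = _ESO_Z
    return _ESO_AMP * np.sin(2 * np.pi * (np.asarray(z) - z0) / (4.0 * (z1 - z0)))


def _branch_centers(z: float) -> list[tuple[float, float]]:
    off = _BRANCH_OFFSET + _BRANCH_SLOPE * (_CARINA_Z - z)
    return [(_PBT_XY[0] + off, _PBT_XY[1]), (_PBT_XY[0] - off, _PBT_XY[1])]


def _heart_slices(grid: Grid3D, scale: float) -> list[tuple[float, list[np.ndarray]]]:
    cx, cy, cz = _HEART_CENTER
    a, b, c = (s * scale for s in _HEART_SEMIAXES)
    out = []
    for z in grid.z_centers:
        u = (z - cz) / c
        if abs(u) >= 1.0:
            continue
        w = math.sqrt(1.0 - u * u)
        out.append((float(z), [_ellipse(cx, cy, a * w, b * w)]))
    return out


def _eso_slices(grid: Grid3D, radius: float) -> list[tuple[float, list[np.ndarray]]]:
    out = []
    for z in grid.z_centers:
        if _ESO_Z[0] <= z <= _ESO_Z[1]:
            out.append((float(z), [_circle(float(_eso_center_x(z)), _ESO_Y, radius)]))
    return out


def _pbt_slices(grid: Grid3D, scale: float) -> list[tuple[float, list[np.ndarray]]]:
    rt = _TRACHEA_RADIUS * scale
    rb = _BRANCH_RADIUS * scale
    out = []
    for z in grid.z_centers:
        if z >= _CARINA_Z:
            out.append((float(z), [_circle(*_PBT_XY, rt)]))
        elif z >= _BRANCH_Z_MIN:
            polys = [_circle(cx, cy, rb) for cx, cy in _branch_centers(z)]
            out.append((float(z), polys))
    return out


def polygon_volume_cm3(structure: Structure, dz: float) -> float:
    """Analytic structure volume: shoelace polygon areas times slice spacing."""
    total = 0.0
    for _, polys in structure.slices:
        for poly in polys:
            x, y = np.asarray(poly, float).T
            total += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return total * dz / 1000.0


def _scale_for_volume(target: float | None, base_volume: float, power: float) -> float:
    if target is None:
        return 1.0
    if target <= 0:
        raise ValidationError("organ target volume must be positive")
    return (target / base_volume) ** power


# ---------------------------------------------------------------------------
# case construction
# ---------------------------------------------------------------------------


def build_structures(spec: PhantomSpec) -> dict[str, Structure]:
    """The three organ structures plus BODY, with exact volume targeting."""
    grid = spec.grid()
    dz = grid.spacing[2]

    base_heart = polygon_volume_cm3(Structure("h", _heart_slices(grid, 1.0)), dz)
    heart_scale = _scale_for_volume(spec.heart_volume, base_heart, 1.0 / 3.0)
    heart = Structure(spec.organ_names[HEART_NAME], _heart_slices(grid, heart_scale))

    base_eso = polygon_volume_cm3(Structure("e", _eso_slices(grid, _ESO_RADIUS)), dz)
    eso_radius = _ESO_RADIUS * _scale_for_volume(spec.eso_volume, base_eso, 0.5)
    eso = Structure(spec.organ_names[ESO_NAME], _eso_slices(grid, eso_radius))

    base_pbt = polygon_volume_cm3(Structure("p", _pbt_slices(grid, 1.0)), dz)
    pbt_scale = _scale_for_volume(spec.pbt_volume, base_pbt, 0.5)
    pbt = Structure(spec.organ_names[PBT_NAME], _pbt_slices(grid, pbt_scale))

    body = Structure(
        BODY_NAME,
        [(float(z), [_circle(0.0, 0.0, spec.body_radius)]) for z in grid.z_centers],
        interpretation="reference",
    )
    return {
        PBT_NAME: pbt,
        HEART_NAME: heart,
        ESO_NAME: eso,
        BODY_NAME: body,
        "_heart_scale": heart_scale,  # type: ignore[dict-item]
        "_eso_radius": eso_radius,  # type: ignore[dict-item]
        "_pbt_scale": pbt_scale,  # type: ignore[dict-item]
    }


def build_ct(spec: PhantomSpec, internals: dict) -> CTImageSeries:
    """Paint the CT volume consistently with the generated contours."""
    grid = spec.grid()
    X = grid.x_centers[None, None, :]
    Y = grid.y_centers[None, :, None]
    Z = grid.z_centers[:, None, None]
    hu = np.full(grid.array_shape, HU_AIR, dtype=np.int16)

    hu[np.broadcast_to((X**2 + Y**2) <= spec.body_radius**2, grid.array_shape)] = HU_BODY

    for cx, cy, cz in _LUNG_CENTERS:
        a, b, c = _LUNG_SEMIAXES
        inside = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
        hu[inside] = HU_LUNG

    hx, hy, hz = _HEART_CENTER
    a, b, c = (s * internals["_heart_scale"] for s in _HEART_SEMIAXES)
    hu[((X - hx) / a) ** 2 + ((Y - hy) / b) ** 2 + ((Z - hz) / c) ** 2 <= 1.0] = HU_HEART

    ex = _eso_center_x(grid.z_centers)[:, None, None]
    in_z = (Z >= _ESO_Z[0]) & (Z <= _ESO_Z[1])
    hu[in_z & ((X - ex) ** 2 + (Y - _ESO_Y) ** 2 <= internals["_eso_radius"] ** 2)] = HU_ESO

    rt = _TRACHEA_RADIUS * internals["_pbt_scale"]
    rb = _BRANCH_RADIUS * internals["_pbt_scale"]
    tx, ty = _PBT_XY
    hu[(Z >= _CARINA_Z) & ((X - tx) ** 2 + (Y - ty) ** 2 <= rt**2)] = HU_AIR
    off = _BRANCH_OFFSET + _BRANCH_SLOPE * (_CARINA_Z - grid.z_centers)
    off = off[:, None, None]
    in_branch_z = (Z >= _BRANCH_Z_MIN) & (Z < _CARINA_Z)
    for sign in (+1, -1):
        hu[in_branch_z & ((X - (tx + sign * off)) ** 2 + (Y - ty) ** 2 <= rb**2)] = HU_AIR

    return CTImageSeries(series_id=f"{spec.patient_id}-CT", grid=grid, values=hu)


def build_dose(spec: PhantomSpec) -> DoseGrid:
    grid = spec.grid()
    model = spec.dose_model
    kind = model["kind"]
    X = grid.x_centers[None, None, :]
    Y = grid.y_centers[None, :, None]
    Z = grid.z_centers[:, None, None]
    if kind == "uniform":
        values = np.full(grid.array_shape, float(model["dose"]))
    elif kind == "gradient":
        axis = {"x": X, "y": Y, "z": Z}[model.get("axis", "x")]
        center = {"x": np.mean(grid.x_centers), "y": np.mean(grid.y_centers),
                  "z": np.mean(grid.z_centers)}[model.get("axis", "x")]
        values = spec.prescribed_dose + model["gradient"] * (axis - center)
        values = np.clip(np.broadcast_to(values, grid.array_shape), 0.0, None).copy()
    elif kind == "target":
        cx, cy, cz = model.get("center", _HEART_CENTER)
        radius = model.get("radius", 40.0)
        falloff = model.get("falloff", 25.0)
        r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        excess = np.clip(r - radius, 0.0, None)
        values = spec.prescribed_dose * np.exp(-((excess / falloff) ** 2))
    else:
        raise ValidationError(f"unknown dose model kind {kind!r}")
    return DoseGrid(grid=grid, values=values)


def make_case(spec: PhantomSpec, out_dir: str | Path | None = None) -> RTCase:
    """Build the in-memory case; optionally write its DICOM files.

    Deterministic: the same spec always produces the same files.
    """
    internals = build_structures(spec)
    structures = [internals[PBT_NAME], internals[HEART_NAME], internals[ESO_NAME],
                  internals[BODY_NAME]]
    ct = build_ct(spec, internals)
    dose = build_dose(spec)
    plans = [
        TreatmentPlanRecord(
            plan_id=spec.plan_id,
            prescribed_dose=spec.prescribed_dose,
            planned_fractions=spec.planned_fractions,
            delivered_fractions=spec.delivered_fractions,
        )
    ]
    doses = {spec.plan_id: dose}
    if spec.extra_plan:
        boost_id = spec.plan_id + "B"
        plans.append(
            TreatmentPlanRecord(
                plan_id=boost_id,
                prescribed_dose=10.0,
                planned_fractions=5,
                delivered_fractions=5,
            )
        )
        doses[boost_id] = DoseGrid(grid=dose.grid, values=dose.values * (10.0 / spec.prescribed_dose))
    case = RTCase(
        patient_id=spec.patient_id,
        ct=ct,
        structure_sets=[StructureSet(structures=structures, label="StructureSet")],
        plans=plans,
        doses=doses,
    )
    if out_dir is not None:
        rt_model.write_case(case, Path(out_dir) / spec.patient_id)
    return case


# ---------------------------------------------------------------------------
# structure perturbation (synthetic "autosegmentations" with known errors)
# ---------------------------------------------------------------------------


def perturb_structure(
    structure: Structure,
    op: str,
    magnitude: float,
    direction: tuple[float, float] = (1.0, 0.0),
) -> Structure:
    """Translate, dilate, or erode a contoured structure in-plane.

    ``translate`` shifts every vertex by ``magnitude`` mm along
    ``direction``; ``dilate``/``erode`` offset each slice polygon outward
    or inward by ``magnitude`` along its normals.  Slices collapsing
    under erosion are dropped with a warning; if all collapse, an error
    is raised.  Magnitude 0 is the identity.
    """
    if magnitude == 0:
        return structure
    if op == "translate":
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return structure.translated(dx=magnitude * d[0], dy=magnitude * d[1])
    if op not in ("dilate", "erode"):
        raise ValidationError(f"unknown perturbation {op!r}")
    offset = magnitude if op == "dilate" else -magnitude
    new_slices = []
    for z, polys in structure.slices:
        new_polys = []
        for poly in polys:
            buffed = shapely.geometry.Polygon(poly).buffer(offset, quad_segs=8)
            if buffed.is_empty or buffed.area <= 0:
                continue
            if buffed.geom_type == "MultiPolygon":
                buffed = max(buffed.geoms, key=lambda g: g.area)
            coords = np.asarray(buffed.exterior.coords)[:-1]
            if coords.shape[0] >= 3:
                new_polys.append(coords)
        if new_polys:
            new_slices.append((z, new_polys))
        else:
            warnings.warn(f"slice z={z:.2f} collapsed under {op} {magnitude} mm", RuntimeWarning)
    if not new_slices:
        raise ValidationError(f"structure {structure.name!r} fully collapsed under {op}")
    return Structure(structure.name, new_slices, structure.interpretation)


# ---------------------------------------------------------------------------
# cohorts and error injection
# ---------------------------------------------------------------------------

VALID_ERROR_KINDS = (
    "drop_file",
    "duplicate_plan",
    "rename_collision",
    "dose_offset",
    "structure_shift",
    "hu_corruption",
    "volume_outlier",
    "unexpected_oar_id",
)

#: which workflow process is designed to catch each error kind
ERROR_DETECTED_BY = {
    "drop_file": "qc_extraction",
    "duplicate_plan": "qc_cleanup_injection",
    "rename_collision": "qc_cleanup_injection",
    "dose_offset": "qc_cleanup_injection",
    "structure_shift": "qc_cleanup_injection",
    "hu_corruption": "qc_cleanup_injection",
    "volume_outlier": "qc_autoseg",
    "unexpected_oar_id": "cleanup",
}

_POST_CLEANUP_KINDS = (
    "duplicate_plan",
    "rename_collision",
    "dose_offset",
    "structure_shift",
    "hu_corruption",
)


@dataclass
class ErrorInjection:
    """One deliberately introduced data error, traceable in the ledger."""

    kind: str
    patient_index: int  # 0-based index into the generated cohort
    organ: str = HEART_NAME
    magnitude: float = 0.0  # Gy / mm / SD multiple, by kind

    def __post_init__(self):
        if self.kind not in VALID_ERROR_KINDS:
            raise ValidationError(f"unknown error kind {self.kind!r}")


@dataclass
class CohortPaths:
    source_store: Path
    cohort_csv: Path
    nomenclature_csv: Path
    ledger_json: Path
    volume_stats_json: Path


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, bound_sd: float) -> float:
    while True:
        v = rng.normal(mean, sd)
        if abs(v - mean) <= bound_sd * sd and v > 0:
            return v


def make_cohort(
    n: int,
    out_dir: str | Path,
    population_params: dict | None = None,
    error_injections: list[ErrorInjection] | None = None,
    seed: int = 0,
) -> CohortPaths:
    """Generate a source store of ``n`` phantom patients plus sidecars.

    Writes the cohort list CSV, the organ nomenclature CSV, a JSON record
    of the per-stratum volume parameters, and the truth ledger describing
    every injected error (kind, patient, the QC process designed to
    detect it).  Source-level errors (``drop_file``, ``volume_outlier``,
    ``unexpected_oar_id``) are applied here; post-cleanup errors are
    recorded for the workflow runner to apply just before injection.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    out_dir = Path(out_dir)
    source = out_dir / "source_store"
    source.mkdir(parents=True, exist_ok=True)
    population = population_params or DEFAULT_POPULATION
    injections = error_injections or []
    for inj in injections:
        if not 0 <= inj.patient_index < n:
            raise ValidationError(f"injection patient index {inj.patient_index} out of range")
    rng = np.random.default_rng(seed)

    rows = []
    ledger_entries = []
    for i in range(n):
        pid = f"PT{i + 1:04d}"
        sex = "M" if i % 2 == 0 else "F"
        volumes = {
            organ: _truncated_normal(rng, *population[(organ, sex)], CLEAN_TRUNCATION_SD)
            for organ in ORGAN_NAMES
        }
        organ_names = {o: ORGAN_ALIASES[o][i % len(ORGAN_ALIASES[o])] for o in ORGAN_NAMES}
        delivered = 33 if i % 5 else 30  # every fifth course is shortened

        my_injections = [inj for inj in injections if inj.patient_index == i]
        for inj in my_injections:
            if inj.kind == "volume_outlier":
                mean, sd = population[(inj.organ, sex)]
                k = inj.magnitude or 4.0
                volumes[inj.organ] = mean + k * sd
            elif inj.kind == "unexpected_oar_id":
                organ_names[inj.organ] = "Unknown_OAR_77"

        needs_two_plans = any(inj.kind == "rename_collision" for inj in my_injections)
        spec = PhantomSpec(
            patient_id=pid,
            sex=sex,
            course_id=f"C{i + 1:03d}",
            plan_id=f"Plan_{i + 1}",
            delivered_fractions=delivered,
            heart_volume=volumes[HEART_NAME],
            eso_volume=volumes[ESO_NAME],
            pbt_volume=volumes[PBT_NAME],
            dose_model={"kind": "target", "center": _HEART_CENTER, "radius": 40.0, "falloff": 60.0},
            organ_names=organ_names,
            extra_plan=needs_two_plans,
        )
        case = make_case(spec, source)

        for plan in case.plans:
            rows.append(
                {
                    "patient_id": pid,
                    "course_id": spec.course_id,
                    "plan_id": plan.plan_id,
                    "delivered_fractions": plan.delivered_fractions,
                    "reference_structure_name": BODY_NAME,
                    "sex": sex,
                }
            )

        for inj in my_injections:
            if inj.kind == "drop_file":
                # lock the plan file: extraction will skip it
                (source / pid / EXTRACTION_LOCKS_FILE).write_text(json.dumps(["rp_0.dcm"]))
            entry = asdict(inj)
            entry["patient_id"] = pid
            entry["detected_by"] = ERROR_DETECTED_BY[inj.kind]
            entry["post_cleanup"] = inj.kind in _POST_CLEANUP_KINDS
            ledger_entries.append(entry)

    cohort_csv = out_dir / "cohort.csv"
    pd.DataFrame(rows, columns=COHORT_LIST_COLUMNS).to_csv(cohort_csv, index=False)

    nomenclature_csv = out_dir / "nomenclature.csv"
    rules = [(alias, std) for std, aliases in ORGAN_ALIASES.items() for alias in aliases]
    NomenclatureMap(rules=rules).to_csv(nomenclature_csv)

    stats_json = out_dir / "volume_stats.json"
    stats_json.write_text(
        json.dumps(
            [
                {"organ": organ, "sex": sex, "mean": m, "sd": s, "n": 100}
                for (organ, sex), (m, s) in population.items()
            ],
            indent=1,
        )
    )

    ledger_json = out_dir / "ledger.json"
    ledger_json.write_text(json.dumps({"n": n, "seed": seed, "errors": ledger_entries}, indent=1))

    return CohortPaths(
        source_store=source,
        cohort_csv=cohort_csv,
        nomenclature_csv=nomenclature_csv,
        ledger_json=ledger_json,
        volume_stats_json=stats_json,
    )


# ---------------------------------------------------------------------------
# post-cleanup fault application (file-level edits on the cleaned case)
# ---------------------------------------------------------------------------


def apply_post_cleanup_fault(entry: dict, case_dir: str | Path, reference_centroid) -> None:
    """Apply one ledger-recorded fault to a cleaned case directory.

    These simulate corruption between cleanup and injection; each is
    crafted so that exactly the integrity check designed for it trips.
    """
    case_dir = Path(case_dir)
    kind = entry["kind"]
    if kind == "duplicate_plan":
        ds = pydicom.dcmread(case_dir / "rp_0.dcm")
        dup_uid = make_uid(str(ds.PatientID), "duplicate-plan")
        ds.SOPInstanceUID = dup_uid
        ds.file_meta.MediaStorageSOPInstanceUID = dup_uid
        ds.save_as(case_dir / "rp_dup.dcm", enforce_file_format=True)
    elif kind == "rename_collision":
        first = pydicom.dcmread(case_dir / "rp_0.dcm")
        second = pydicom.dcmread(case_dir / "rp_1.dcm")
        second.RTPlanLabel = first.RTPlanLabel
        second.save_as(case_dir / "rp_1.dcm", enforce_file_format=True)
    elif kind == "dose_offset":
        ds = pydicom.dcmread(case_dir / "rd_0.dcm")
        scaling = float(ds.DoseGridScaling)
        offset_gy = entry.get("magnitude") or 0.3
        stored = ds.pixel_array.astype(np.int64) + round(offset_gy / scaling)
        ds.PixelData = np.clip(stored, 0, 2**32 - 1).astype(np.uint32).tobytes()
        ds.save_as(case_dir / "rd_0.dcm", enforce_file_format=True)
    elif kind == "structure_shift":
        shift = entry.get("magnitude") or 1.0
        path = next(p for p in sorted(case_dir.glob("rs_*.dcm")))
        ds = pydicom.dcmread(path)
        names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
        for rc in ds.ROIContourSequence:
            if names[int(rc.ReferencedROINumber)] != BODY_NAME:
                continue
            for c in rc.ContourSequence:
                pts = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
                pts[:, 0] += shift
                c.ContourData = [f"{v:.6f}" for v in pts.ravel()]
        ds.save_as(path, enforce_file_format=True)
    elif kind == "hu_corruption":
        cx, cy, cz = reference_centroid
        # bump the voxel nearest the reference centroid, using the same
        # nearest-index rule (round half to even) as the integrity check
        files, zs = [], []
        for p in sorted(case_dir.glob("ct_*.dcm")):
            files.append(p)
            zs.append(float(pydicom.dcmread(p, stop_before_pixels=True).ImagePositionPatient[2]))
        order = np.argsort(zs)
        files = [files[i] for i in order]
        zs = np.array(zs)[order]
        dz = zs[1] - zs[0] if len(zs) > 1 else 1.0
        iz = int(np.clip(round((cz - zs[0]) / dz), 0, len(files) - 1))
        ds = pydicom.dcmread(files[iz])
        dy, dx = (float(v) for v in ds.PixelSpacing)
        ix = int(round((cx - float(ds.ImagePositionPatient[0])) / dx))
        iy = int(round((cy - float(ds.ImagePositionPatient[1])) / dy))
        arr = ds.pixel_array
        arr[iy, ix] += 300
        ds.PixelData = arr.tobytes()
        ds.save_as(files[iz], enforce_file_format=True)
    else:
        raise ValidationError(f"fault {kind!r} is not a post-cleanup fault")
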