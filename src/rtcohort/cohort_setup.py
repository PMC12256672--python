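"""The Setup process: cohort manifest and pseudonymization key.

From a cohort list (CSV: one row per treatment plan) and the source file
store, Setup builds a manifest holding, per patient: the pseudonym, the
plans with planned/delivered fraction counts, the expected DICOM file
counts per modality, and a fingerprint of a chosen *reference
delineation* — its course mean dose, voxel centroid, and the CT number
at the centroid — later used to verify data integrity after cleanup and
injection.  It also mints the pseudonymization key: a bijective
source-id <-> pseudonym map plus the salt used for UID remapping.

Pseudonyms are human-auditable fixed-prefix sequence numbers assigned by
sorted source id; the salt only enters UID remapping, so the manifest is
a pure function of (cohort list, source store content, salt).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rtcohort import dosimetry, geometry
from rtcohort.rt_model import RTCase, ValidationError, read_case

COHORT_LIST_COLUMNS = [
    "patient_id",
    "course_id",
    "plan_id",
    "delivered_fractions",
    "reference_structure_name",
    "sex",
]


@dataclass
class PseudonymizationKey:
    """Bijective source-patient-id <-> pseudonym map + UID salt."""

    forward: dict[str, str]  # source id -> pseudonym
    uid_salt: str

    def __post_init__(self):
        if len(set(self.forward.values())) != len(self.forward):
            raise ValidationError("pseudonyms are not unique")
        self.reverse = {v: k for k, v in self.forward.items()}

    def pseudonym(self, source_id: str) -> str:
        return self.forward[source_id]

    def to_csv(self, path: str | Path) -> None:
        """Write the key file with owner-only permissions."""
        path = Path(path)
        df = pd.DataFrame(
            {"source_patient_id": list(self.forward), "pseudonym": list(self.forward.values())}
        )
        df.to_csv(path, index=False)
        path.chmod(0o600)
        salt_path = path.with_suffix(".salt")
        salt_path.write_text(self.uid_salt)
        salt_path.chmod(0o600)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PseudonymizationKey":
        path = Path(path)
        df = pd.read_csv(path, dtype=str)
        salt = path.with_suffix(".salt").read_text()
        return cls(forward=dict(zip(df.source_patient_id, df.pseudonym)), uid_salt=salt)


def make_key(patient_ids: list[str], salt: str, prefix: str = "RT") -> PseudonymizationKey:
    """Deterministic pseudonym assignment: ``<prefix><seq>`` by sorted id."""
    ids = [str(i) for i in patient_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids")
    width = max(4, len(str(len(ids))))
    forward = {pid: f"{prefix}{i:0{width}d}" for i, pid in enumerate(sorted(ids), start=1)}
    return PseudonymizationKey(forward=forward, uid_salt=salt)


@dataclass
class ReferenceDelineationRecord:
    structure_name: str
    mean_dose: float  # Gy, course sum over listed plans (clinical, pre-rescale)
    per_plan_mean_dose: dict[str, float]
    centroid: tuple[float, float, float]  # mm
    ct_number_at_centroid: int  # HU of the CT voxel nearest the centroid


@dataclass
class PlanEntry:
    plan_id: str
    planned_fractions: int
    delivered_fractions: int
    prescribed_dose: float


@dataclass
class PatientEntry:
    pseudonym: str
    course_id: str
    sex: str
    plans: list[PlanEntry]
    expected_file_counts: dict[str, int]  # modality -> count
    reference: ReferenceDelineationRecord | None
    flags: list[str] = field(default_factory=list)


@dataclass
class CohortManifest:
    """Per-patient expected content; keyed by pseudonym (no source ids)."""

    patients: dict[str, PatientEntry]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({k: asdict(v) for k, v in self.patients.items()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        raw = json.loads(Path(path).read_text())
        patients = {}
        for k, v in raw.items():
            ref = v.pop("reference")
            plans = [PlanEntry(**p) for p in v.pop("plans")]
            patients[k] = PatientEntry(
                plans=plans,
                reference=(
                    ReferenceDelineationRecord(
                        structure_name=ref["structure_name"],
                        mean_dose=ref["mean_dose"],
                        per_plan_mean_dose=ref["per_plan_mean_dose"],
                        centroid=tuple(ref["centroid"]),
                        ct_number_at_centroid=ref["ct_number_at_centroid"],
                    )
                    if ref
                    else None
                ),
                **v,
            )
        return cls(patients=patients)


@dataclass
class BuildReport:
    unresolved_patients: list[str] = field(default_factory=list)
    flagged_patients: dict[str, list[str]] = field(default_factory=dict)


def reference_fingerprint(case: RTCase, structure_name: str) -> ReferenceDelineationRecord | None:
    """Mean dose / centroid / HU fingerprint of the named structure.

    Returns None when the structure is absent.  The mean dose is the
    course sum of the per-plan mean doses over the structure.
    """
    if case.structure_set is None:
        return None
    structure = case.structure_set.find(structure_name)
    if structure is None:
        return None
    mask = geometry.rasterize(structure, case.ct.grid)
    if mask.n_voxels == 0:
        return None
    cen = geometry.centroid(mask)
    per_plan = {}
    for plan in case.plans:
        dose = case.doses.get(plan.plan_id)
        if dose is not None:
            per_plan[plan.plan_id] = dosimetry.d_mean(dosimetry.voxel_doses(mask, dose))
    g = case.ct.grid
    ix = int(np.clip(round((cen[0] - g.origin[0]) / g.spacing[0]), 0, g.shape[0] - 1))
    iy = int(np.clip(round((cen[1] - g.origin[1]) / g.spacing[1]), 0, g.shape[1] - 1))
    iz = int(np.clip(round((cen[2] - g.origin[2]) / g.spacing[2]), 0, g.shape[2] - 1))
    hu = int(case.ct.values[iz, iy, ix])
    return ReferenceDelineationRecord(
        structure_name=structure_name,
        mean_dose=float(sum(per_plan.values())),
        per_plan_mean_dose=per_plan,
        centroid=tuple(float(v) for v in cen),
        ct_number_at_centroid=hu,
    )


def read_cohort_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "course_id": str, "plan_id": str, "sex": str})
    missing = [c for c in COHORT_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort list missing columns: {missing}")
    return df


def build_manifest(
    cohort_list: pd.DataFrame | str | Path,
    source_store: str | Path,
    key: PseudonymizationKey,
) -> tuple[CohortManifest, BuildReport]:
    """Build the manifest from the cohort list and the source store.

    Unresolvable patients are listed in the build report, never silently
    dropped; a misspelled/absent reference structure flags the entry.
    """
    if not isinstance(cohort_list, pd.DataFrame):
        cohort_list = read_cohort_list(cohort_list)
    source_store = Path(source_store)
    report = BuildReport()
    patients: dict[str, PatientEntry] = {}

    for patient_id, rows in cohort_list.groupby("patient_id", sort=True):
        patient_id = str(patient_id)
        case_dir = source_store / patient_id
        if not case_dir.is_dir():
            report.unresolved_patients.append(patient_id)
            continue
        case = read_case(case_dir)
        pseudonym = key.pseudonym(patient_id)
        flags: list[str] = []

        listed_plans = {str(r.plan_id): int(r.delivered_fractions) for r in rows.itertuples()}
        plan_entries: list[PlanEntry] = []
        for plan in case.plans:
            if plan.plan_id in listed_plans:
                plan_entries.append(
                    PlanEntry(
                        plan_id=plan.plan_id,
                        planned_fractions=plan.planned_fractions,
                        delivered_fractions=listed_plans[plan.plan_id],
                        prescribed_dose=plan.prescribed_dose,
                    )
                )
        for plan_id in listed_plans:
            if plan_id not in {p.plan_id for p in plan_entries}:
                flags.append(f"listed plan {plan_id!r} not found in source case")

        ref_name = str(rows.iloc[0].reference_structure_name)
        reference = reference_fingerprint(case, ref_name)
        if reference is None:
            flags.append(f"reference structure {ref_name!r} absent")

        counts = {
            "CT": case.ct.grid.shape[2],
            "RTSTRUCT": len(case.structure_sets),
            "RTPLAN": len(case.plans),
            "RTDOSE": len(case.doses),
        }
        patients[pseudonym] = PatientEntry(
            pseudonym=pseudonym,
            course_id=str(rows.iloc[0].course_id),
            sex=str(rows.iloc[0].sex),
            plans=plan_entries,
            expected_file_counts=counts,
            reference=reference,
            flags=flags,
        )
        if flags:
            report.flagged_patients[pseudonym] = flags

    return CohortManifest(patients=patients), report
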