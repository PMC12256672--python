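"""The three quality-control processes.

* ``qc_extraction`` — per patient, per modality, compares the number of
  files in the extracted store against what the manifest says should
  exist.
* ``qc_cleanup_injection`` — verifies the research store: patient
  present, plan count and plan ids correct, every plan carries dose, and
  the reference-delineation fingerprint matches the manifest — the
  course mean dose within 0.1 Gy (after the cleanup delivered/planned
  rescale), the centroid within 0.5 mm, and the CT number at the
  centroid exactly (the same voxel is read on both sides, so any
  difference means geometry or data corruption).
* ``qc_autoseg`` — flags autosegmentations whose volume falls outside
  mean +/- k*SD (default k = 3, the 99.7% interval) of the per-organ,
  per-sex volume distribution fitted from training delineations.

QCs emit findings, never exceptions: a missing stratum is reported as
"not evaluable", not silently passed.  Volumes exactly on the +/- k*SD
boundary pass; only strictly outside flags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom

from rtcohort import dosimetry, geometry
from rtcohort.cohort_setup import CohortManifest
from rtcohort.curation import NomenclatureMap
from rtcohort.rt_model import RTModelError, ValidationError, read_case

PASS, FLAG, NOT_EVALUABLE = "pass", "flag", "not_evaluable"


@dataclass
class QCConfig:
    dose_tol: float = 0.1  # Gy
    centroid_tol: float = 0.5  # mm
    volume_sd_multiplier: float = 3.0
    min_training_n: int = 20

    def __post_init__(self):
        if min(self.dose_tol, self.centroid_tol, self.volume_sd_multiplier) <= 0:
            raise ValidationError("QC tolerances must be positive")


@dataclass
class Finding:
    patient: str
    check_id: str
    status: str  # pass | flag | not_evaluable
    observed: object = None
    expected: object = None
    message: str = ""


@dataclass
class QCReport:
    process: str
    findings: list[Finding] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.findings.append(Finding(*args, **kwargs))

    @property
    def flags(self) -> list[Finding]:
        return [f for f in self.findings if f.status != PASS]

    @property
    def n_flags(self) -> int:
        return len(self.flags)

    def flagged_patients(self) -> set[str]:
        return {f.patient for f in self.flags}

    def patient_passed(self, patient: str) -> bool:
        return all(f.status == PASS for f in self.findings if f.patient == patient)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(f) for f in self.findings])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"process": self.process, "findings": [asdict(f) for f in self.findings]},
                       indent=1, default=str)
        )


# --------------------------------------------------------------------------
# QC of Extraction
# --------------------------------------------------------------------------


def _count_modalities(case_dir: Path) -> dict[str, int]:
    counts = {"CT": 0, "RTSTRUCT": 0, "RTPLAN": 0, "RTDOSE": 0}
    for path in case_dir.glob("*.dcm"):
        ds = pydicom.dcmread(path, stop_before_pixels=True, specific_tags=["Modality"])
        m = str(ds.Modality)
        counts[m] = counts.get(m, 0) + 1
    return counts


def qc_extraction(manifest: CohortManifest, extracted_store: str | Path) -> QCReport:
    """File counts per modality vs the manifest; mismatches flag."""
    store = Path(extracted_store)
    report = QCReport(process="qc_extraction")
    for pseudonym, entry in manifest.patients.items():
        case_dir = store / pseudonym
        if not case_dir.is_dir():
            report.add(pseudonym, "extracted_present", FLAG, observed=0, expected=1,
                       message="no extracted data")
            continue
        observed = _count_modalities(case_dir)
        for modality, expected in entry.expected_file_counts.items():
            got = observed.get(modality, 0)
            status = PASS if got == expected else FLAG
            msg = "" if status == PASS else (
                f"{'missing' if got < expected else 'surplus'} {modality} files"
            )
            report.add(pseudonym, f"file_count_{modality}", status,
                       observed=got, expected=expected, message=msg)
    return report


# --------------------------------------------------------------------------
# QC of Cleanup & Injection
# --------------------------------------------------------------------------


def qc_cleanup_injection(
    manifest: CohortManifest,
    research_store: str | Path,
    config: QCConfig,
    nomenclature: NomenclatureMap,
) -> QCReport:
    """Integrity checks of the research store against the manifest."""
    store = Path(research_store)
    report = QCReport(process="qc_cleanup_injection")
    for pseudonym, entry in manifest.patients.items():
        case_dir = store / pseudonym
        if not case_dir.is_dir():
            report.add(pseudonym, "patient_created", FLAG, observed=0, expected=1,
                       message="patient missing from research store")
            continue
        report.add(pseudonym, "patient_created", PASS, observed=1, expected=1)
        try:
            case = read_case(case_dir)
        except RTModelError as exc:
            report.add(pseudonym, "case_readable", FLAG, message=str(exc))
            continue

        expected_ids = [
            nomenclature.plan_id_template.format(course=entry.course_id, seq=i)
            for i in range(1, len(entry.plans) + 1)
        ]
        got_ids = [p.plan_id for p in case.plans]
        n_ok = len(got_ids) == len(expected_ids)
        report.add(pseudonym, "plan_count", PASS if n_ok else FLAG,
                   observed=len(got_ids), expected=len(expected_ids),
                   message="" if n_ok else "wrong number of treatment plans")
        ids_ok = sorted(got_ids) == sorted(expected_ids) and len(set(got_ids)) == len(got_ids)
        report.add(pseudonym, "plan_ids", PASS if ids_ok else FLAG,
                   observed=sorted(got_ids), expected=sorted(expected_ids),
                   message="" if ids_ok else "plan ids differ from template or collide")

        for plan in case.plans:
            has_dose = plan.plan_id in case.doses
            report.add(pseudonym, "plan_has_dose", PASS if has_dose else FLAG,
                       observed=has_dose, expected=True,
                       message="" if has_dose else f"plan {plan.plan_id!r} has no dose")

        ref = entry.reference
        if ref is None:
            report.add(pseudonym, "reference_dose", NOT_EVALUABLE,
                       message="no reference delineation in manifest")
            continue
        if case.structure_set is None or case.structure_set.find(ref.structure_name) is None:
            report.add(pseudonym, "reference_dose", FLAG,
                       message=f"reference structure {ref.structure_name!r} missing")
            continue
        structure = case.structure_set.find(ref.structure_name)
        mask = geometry.rasterize(structure, case.ct.grid)
        if mask.n_voxels == 0:
            report.add(pseudonym, "reference_dose", FLAG, message="empty reference structure")
            continue

        # expected course dose after the cleanup rescale
        expected_dose = 0.0
        for p in entry.plans:
            md = ref.per_plan_mean_dose.get(p.plan_id, 0.0)
            expected_dose += md * p.delivered_fractions / p.planned_fractions
        observed_dose = 0.0
        for plan_id, dose in case.doses.items():
            observed_dose += dosimetry.d_mean(dosimetry.voxel_doses(mask, dose))
        dose_ok = abs(observed_dose - expected_dose) <= config.dose_tol
        report.add(pseudonym, "reference_dose", PASS if dose_ok else FLAG,
                   observed=round(observed_dose, 4), expected=round(expected_dose, 4),
                   message="" if dose_ok else
                   f"reference mean dose off by {abs(observed_dose - expected_dose):.3f} Gy")

        cen = geometry.centroid(mask)
        shift = float(np.linalg.norm(np.asarray(cen) - np.asarray(ref.centroid)))
        cen_ok = shift <= config.centroid_tol
        report.add(pseudonym, "reference_centroid", PASS if cen_ok else FLAG,
                   observed=[round(v, 3) for v in cen],
                   expected=[round(v, 3) for v in ref.centroid],
                   message="" if cen_ok else f"centroid moved {shift:.3f} mm")

        g = case.ct.grid
        ix = int(np.clip(round((ref.centroid[0] - g.origin[0]) / g.spacing[0]), 0, g.shape[0] - 1))
        iy = int(np.clip(round((ref.centroid[1] - g.origin[1]) / g.spacing[1]), 0, g.shape[1] - 1))
        iz = int(np.clip(round((ref.centroid[2] - g.origin[2]) / g.spacing[2]), 0, g.shape[2] - 1))
        hu = int(case.ct.values[iz, iy, ix])
        hu_ok = hu == ref.ct_number_at_centroid
        report.add(pseudonym, "reference_ct_number", PASS if hu_ok else FLAG,
                   observed=hu, expected=ref.ct_number_at_centroid,
                   message="" if hu_ok else "CT number at reference centroid changed")
    return report


# --------------------------------------------------------------------------
# QC of AutoSeg
# --------------------------------------------------------------------------


@dataclass
class VolumeStats:
    """Per (organ, sex) volume distribution of training delineations."""

    strata: dict[tuple[str, str], dict]  # -> {mean, sd, n, active}

    def get(self, organ: str, sex: str) -> dict | None:
        return self.strata.get((organ, sex))


def fit_volume_stats(
    training_volumes: pd.DataFrame, min_training_n: int = 20
) -> VolumeStats:
    """Fit per-(organ, sex) mean and sample SD of training volumes (cm^3).

    Expects columns ``organ``, ``sex``, ``volume_cm3``; strata with fewer
    than ``min_training_n`` cases are kept but marked inactive (the
    flagging QC reports them as not evaluable).
    """
    required = {"organ", "sex", "volume_cm3"}
    if not required <= set(training_volumes.columns):
        raise ValidationError(f"training volumes need columns {sorted(required)}")
    if (training_volumes.volume_cm3 <= 0).any():
        raise ValidationError("training volumes must be > 0")
    strata = {}
    for (organ, sex), grp in training_volumes.groupby(["organ", "sex"]):
        v = grp.volume_cm3.to_numpy(float)
        strata[(organ, sex)] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n": int(len(v)),
            "active": len(v) >= min_training_n,
        }
    return VolumeStats(strata=strata)


def volume_stats_from_params(
    params: dict[tuple[str, str], tuple[float, float]], n: int = 100
) -> VolumeStats:
    """VolumeStats directly from known (mean, sd) population parameters."""
    return VolumeStats(
        strata={k: {"mean": m, "sd": s, "n": n, "active": True} for k, (m, s) in params.items()}
    )


def qc_autoseg(
    volumes_by_case: pd.DataFrame, stats: VolumeStats, config: QCConfig
) -> QCReport:
    """Flag autosegmentation volumes strictly outside mean +/- k*SD.

    ``volumes_by_case`` columns: ``patient``, ``organ``, ``sex``,
    ``volume_cm3``.  A stratum missing from ``stats`` (or inactive) is
    reported as not evaluable.
    """
    report = QCReport(process="qc_autoseg")
    k = config.volume_sd_multiplier
    for row in volumes_by_case.itertuples():
        stratum = stats.get(row.organ, row.sex)
        check = f"volume_{row.organ}"
        if stratum is None or not stratum["active"]:
            report.add(row.patient, check, NOT_EVALUABLE, observed=row.volume_cm3,
                       message=f"no active volume statistics for ({row.organ}, {row.sex})")
            continue
        lo = stratum["mean"] - k * stratum["sd"]
        hi = stratum["mean"] + k * stratum["sd"]
        outside = row.volume_cm3 < lo or row.volume_cm3 > hi
        report.add(row.patient, check, FLAG if outside else PASS,
                   observed=round(float(row.volume_cm3), 3),
                   expected=[round(lo, 3), round(hi, 3)],
                   message="" if not outside else
                   f"{row.organ} volume outside mean +/- {k:g} SD for sex {row.sex}")
    return report
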