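"""Extraction, Cleanup, and Injection.

*Extraction* copies a patient's DICOM files out of the source store with
the patient identity replaced by the pseudonym and every instance/series/
study/frame UID remapped by a keyed hash, so that cross-references
between files stay consistent while nothing links back to the source
without the key.  *Cleanup* applies the curation transforms: planned
fractions set to delivered, dose rescaled by delivered/planned, plan ids
rewritten to a structured template, approval statuses dropped to
unapproved, plan-to-plan links removed, and organ names mapped to the
standardized nomenclature.  *Injection* writes files into the research
store, idempotently per object id.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom

from rtcohort import dosimetry
from rtcohort.cohort_setup import PatientEntry, PseudonymizationKey
from rtcohort.rt_model import UID_ROOT, RTCase, Structure, ValidationError

#: filename of the sidecar listing source files that refuse extraction
#: (stands in for OIS-side locks such as plan reference points)
EXTRACTION_LOCKS_FILE = ".extraction_locks.json"

#: UI-valued keywords that are *class* identifiers and must never be remapped
_CLASS_UID_KEYWORDS = {
    "SOPClassUID",
    "ReferencedSOPClassUID",
    "MediaStorageSOPClassUID",
    "TransferSyntaxUID",
    "ImplementationClassUID",
    "FrameIncrementPointer",
}


class CurationError(ValidationError):
    pass


# --------------------------------------------------------------------------
# nomenclature
# --------------------------------------------------------------------------


@dataclass
class NomenclatureMap:
    """Ordered (alias_pattern, standard_name) organ-name mapping.

    Matching is deterministic and auditable: a case-insensitive,
    whitespace/underscore-normalized exact match is tried first, then the
    patterns are applied in order as regular expressions; the first match
    wins.  ``plan_id_template`` renders the structured plan id from the
    course id and the plan's sequence number within the course.
    """

    rules: list[tuple[str, str]]
    plan_id_template: str = "{course}:P{seq}"

    @staticmethod
    def _normalize(name: str) -> str:
        return re.sub(r"[\s_]+", "", name).casefold()

    def map_name(self, name: str) -> str | None:
        norm = self._normalize(name)
        for pattern, standard in self.rules:
            if self._normalize(pattern) == norm:
                return standard
        for pattern, standard in self.rules:
            if re.fullmatch(pattern, name, flags=re.IGNORECASE):
                return standard
        return None

    @property
    def standard_names(self) -> list[str]:
        out = []
        for _, s in self.rules:
            if s not in out:
                out.append(s)
        return out

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "NomenclatureMap":
        df = pd.read_csv(path, dtype=str)
        return cls(rules=list(zip(df.alias_pattern, df.standard_name)), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rules, columns=["alias_pattern", "standard_name"]).to_csv(
            path, index=False
        )


# --------------------------------------------------------------------------
# extraction / pseudonymization
# --------------------------------------------------------------------------


def remap_uid(uid: str, salt: str) -> str:
    """Keyed-hash UID remapping under the package's private root.

    Deterministic in (uid, salt); the source UID is not recoverable
    without the salt.
    """
    h = hashlib.blake2b(uid.encode(), key=salt.encode()[:64], digest_size=16).digest()
    return UID_ROOT + str(10**28 + int.from_bytes(h, "big") % 10**28)


def _remap_dataset_uids(ds, salt: str, seen: dict[str, str]) -> None:
    for elem in ds.iterall():
        if elem.VR == "UI" and elem.keyword not in _CLASS_UID_KEYWORDS and elem.value:
            values = elem.value if isinstance(elem.value, (list, pydicom.multival.MultiValue)) else [elem.value]
            new = []
            for v in values:
                v = str(v)
                mapped = remap_uid(v, salt)
                prior = seen.setdefault(mapped, v)
                if prior != v:
                    raise CurationError(f"UID remap collision: {v} vs {prior}")
                new.append(mapped)
            elem.value = new if len(new) > 1 else new[0]


_IDENTITY_TAGS = [
    "PatientBirthDate",
    "PatientBirthTime",
    "PatientSex",
    "PatientAddress",
    "OtherPatientIDs",
    "OtherPatientNames",
    "ReferringPhysicianName",
    "InstitutionName",
    "AccessionNumber",
]


def pseudonymize_dataset(ds, pseudonym: str, salt: str, seen: dict[str, str]) -> None:
    """Replace patient identity and remap all instance-level UIDs in place."""
    ds.PatientID = pseudonym
    ds.PatientName = pseudonym
    for kw in _IDENTITY_TAGS:
        if kw in ds:
            delattr(ds, kw)
    _remap_dataset_uids(ds, salt, seen)
    if ds.file_meta is not None and "MediaStorageSOPInstanceUID" in ds.file_meta:
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID


def read_extraction_locks(case_dir: Path) -> set[str]:
    lock_file = case_dir / EXTRACTION_LOCKS_FILE
    if lock_file.exists():
        return set(json.loads(lock_file.read_text()))
    return set()


def extract_case(
    patient_id: str,
    source_store: str | Path,
    key: PseudonymizationKey,
    dest_store: str | Path,
) -> list[Path]:
    """Pseudonymize and copy one patient's files into the extracted store.

    Files named in the case's extraction-lock sidecar are skipped (the
    mismatch surfaces later in the extraction QC, mirroring how locked
    OIS objects fail to extract).  Output is deterministic: re-running
    produces byte-identical files.
    """
    case_dir = Path(source_store) / patient_id
    if not case_dir.is_dir():
        raise CurationError(f"patient {patient_id!r} not found in source store")
    pseudonym = key.pseudonym(patient_id)
    dest_dir = Path(dest_store) / pseudonym
    dest_dir.mkdir(parents=True, exist_ok=True)
    locks = read_extraction_locks(case_dir)
    seen: dict[str, str] = {}
    written = []
    for path in sorted(case_dir.glob("*.dcm")):
        if path.name in locks:
            continue
        ds = pydicom.dcmread(path)
        pseudonymize_dataset(ds, pseudonym, key.uid_salt, seen)
        out = dest_dir / path.name
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


# --------------------------------------------------------------------------
# cleanup
# --------------------------------------------------------------------------


@dataclass
class CleanupResult:
    case: RTCase
    flags: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def cleanup_case(
    case: RTCase,
    manifest_entry: PatientEntry,
    nomenclature: NomenclatureMap,
) -> CleanupResult:
    """Apply the cleanup transforms to an extracted case (pure; idempotent).

    Per plan listed in the manifest: planned fractions become the
    delivered count, the dose grid is multiplied by delivered/planned,
    the plan id is rewritten from the template, the approval status is
    set to unapproved and plan links are emptied.  Organ-interpreted
    structures are renamed through the nomenclature; an unmapped organ
    name flags the case.  Zero delivered fractions zero the dose and
    flag rather than error.
    """
    flags: list[str] = []
    log: list[str] = []
    course = manifest_entry.course_id

    new_plans = []
    new_doses = dict(case.doses)
    matched = set()
    for seq, entry in enumerate(manifest_entry.plans, start=1):
        target_id = nomenclature.plan_id_template.format(course=course, seq=seq)
        plan = next((p for p in case.plans if p.plan_id in (entry.plan_id, target_id)), None)
        if plan is None:
            flags.append(f"manifest plan {entry.plan_id!r} not present in case")
            continue
        matched.add(plan.plan_id)
        already_clean = plan.plan_id == target_id
        factor_num, factor_den = entry.delivered_fractions, entry.planned_fractions
        if entry.delivered_fractions == 0:
            flags.append(f"plan {entry.plan_id!r}: zero delivered fractions, dose zeroed")
        dose = case.doses.get(plan.plan_id)
        if dose is not None:
            if not already_clean:
                dose = dosimetry.rescale_dose(dose, factor_den, factor_num)
            new_doses.pop(plan.plan_id, None)
            new_doses[target_id] = dose
        new_plans.append(
            replace(
                plan,
                plan_id=target_id,
                planned_fractions=max(entry.delivered_fractions, 1),
                delivered_fractions=entry.delivered_fractions,
                approval_status="unapproved",
                linked_plan_ids=[],
            )
        )
        log.append(f"plan {entry.plan_id!r} -> {target_id!r} (x {factor_num}/{factor_den})")

    for plan in case.plans:
        if plan.plan_id not in matched and plan.plan_id not in {p.plan_id for p in new_plans}:
            flags.append(f"case plan {plan.plan_id!r} not listed in manifest")
            new_plans.append(replace(plan, approval_status="unapproved", linked_plan_ids=[]))

    ids = [p.plan_id for p in new_plans]
    if len(ids) != len(set(ids)):
        flags.append(f"duplicate plan id after renaming: {sorted(ids)}")

    new_sets = []
    for structure_set in case.structure_sets:
        new_structures: list[Structure] = []
        for s in structure_set.structures:
            if s.interpretation == "organ":
                mapped = nomenclature.map_name(s.name)
                if mapped is None:
                    flags.append(f"unmapped organ name {s.name!r}")
                    new_structures.append(s)
                else:
                    if mapped != s.name:
                        log.append(f"organ {s.name!r} -> {mapped!r}")
                    new_structures.append(replace(s, name=mapped))
            else:
                new_structures.append(s)
        new_sets.append(
            replace(structure_set, structures=new_structures, approval_status="unapproved")
        )

    new_case = RTCase(
        patient_id=case.patient_id,
        ct=case.ct,
        structure_sets=new_sets,
        plans=new_plans,
        doses=new_doses,
    )
    return CleanupResult(case=new_case, flags=flags, log=log)


# --------------------------------------------------------------------------
# injection
# --------------------------------------------------------------------------


@dataclass
class InjectionReceipt:
    written: list[Path] = field(default_factory=list)
    skipped_duplicates: list[Path] = field(default_factory=list)


def inject_case(files: list[str | Path], research_store: str | Path) -> InjectionReceipt:
    """Copy parsed-valid DICOM files into the research store.

    The store holds exactly one copy per SOP instance: re-injecting an
    identical object is a no-op; the same object id with different
    content is an error.  A file that does not parse is rejected by name.
    """
    store = Path(research_store)
    receipt = InjectionReceipt()
    for f in map(Path, files):
        try:
            ds = pydicom.dcmread(f)
            sop_uid = str(ds.SOPInstanceUID)
            modality = str(ds.Modality)
            patient = str(ds.PatientID)
        except Exception as exc:
            raise CurationError(f"corrupted or non-DICOM file {f.name!r}: {exc}") from exc
        dest_dir = store / patient
        dest_dir.mkdir(parents=True, exist_ok=True)
        dest = dest_dir / f"{modality.lower()}_{sop_uid[-16:]}.dcm"
        content = f.read_bytes()
        if dest.exists():
            if dest.read_bytes() == content:
                receipt.skipped_duplicates.append(dest)
                continue
            raise CurationError(f"object id collision with different content: {dest.name}")
        dest.write_bytes(content)
        receipt.written.append(dest)
    return receipt


def referential_integrity(directory: str | Path) -> bool:
    """True iff every ReferencedSOPInstanceUID in the directory resolves
    to a SOPInstanceUID present in the same directory."""
    present: set[str] = set()
    referenced: set[str] = set()
    for path in sorted(Path(directory).glob("*.dcm")):
        ds = pydicom.dcmread(path, stop_before_pixels=True)
        present.add(str(ds.SOPInstanceUID))
        for elem in ds.iterall():
            if elem.keyword == "ReferencedSOPInstanceUID" and elem.value:
                referenced.add(str(elem.value))
    return referenced <= present
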