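"""Setup (manifest + pseudonymization key), Extraction, Cleanup, Injection."""

import numpy as np
import pandas as pd
import pydicom
import pytest

from rtcohort import curation, phantom, rt_model
from rtcohort.cohort_setup import (
    CohortManifest,
    build_manifest,
    make_key,
    reference_fingerprint,
)
from rtcohort.curation import CurationError, NomenclatureMap, cleanup_case, inject_case
from rtcohort.rt_model import ValidationError, read_case


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    paths = phantom.make_cohort(3, out, seed=5)
    return paths


@pytest.fixture(scope="module")
def key(cohort):
    ids = pd.read_csv(cohort.cohort_csv, dtype=str).patient_id.unique().tolist()
    return make_key(ids, salt="unit-salt")


class TestMakeKey:
    def test_deterministic(self):
        ids = ["B2", "A1", "C3"]
        k1, k2 = make_key(ids, "s"), make_key(ids, "s")
        assert k1.forward == k2.forward and k1.uid_salt == k2.uid_salt

    def test_unique_and_ordered_by_sorted_id(self):
        ids = [f"P{i}" for i in range(1000)]
        k = make_key(ids, "s")
        assert len(set(k.forward.values())) == 1000
        assert k.forward[sorted(ids)[0]].endswith("0001")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            make_key(["X", "X"], "s")

    def test_key_roundtrip_via_csv(self, tmp_path):
        k = make_key(["A", "B"], "pepper")
        k.to_csv(tmp_path / "key.csv")
        back = curation.PseudonymizationKey.from_csv(tmp_path / "key.csv")
        assert back.forward == k.forward and back.uid_salt == "pepper"

    def test_different_salt_changes_uid_remap_only(self):
        k1, k2 = make_key(["A"], "s1"), make_key(["A"], "s2")
        assert k1.forward == k2.forward
        uid = "1.2.3.4.5"
        assert curation.remap_uid(uid, "s1") != curation.remap_uid(uid, "s2")


class TestBuildManifest:
    def test_entries_and_fingerprints(self, cohort, key):
        manifest, report = build_manifest(cohort.cohort_csv, cohort.source_store, key)
        assert len(manifest.patients) == 3
        assert not report.unresolved_patients and not report.flagged_patients
        for entry in manifest.patients.values():
            assert entry.reference is not None
            assert entry.reference.mean_dose > 0
            assert entry.expected_file_counts["CT"] == 64
            assert entry.plans[0].delivered_fractions >= 0

    def test_uniform_dose_gives_exact_reference_mean(self, tmp_path):
        spec = phantom.PhantomSpec(
            patient_id="PTU", shape=(32, 32, 16), spacing=(5.0, 5.0, 5.0), body_radius=60.0,
            dose_model={"kind": "uniform", "dose": 2.0},
        )
        case = phantom.make_case(spec, tmp_path)
        ref = reference_fingerprint(case, "BODY")
        assert ref.mean_dose == pytest.approx(2.0, abs=1e-9)

    def test_misspelled_reference_structure_flags(self, cohort, key):
        df = pd.read_csv(cohort.cohort_csv, dtype=str)
        df.loc[0, "reference_structure_name"] = "BODDY"
        manifest, report = build_manifest(df, cohort.source_store, key)
        pseudonym = key.pseudonym(df.loc[0, "patient_id"])
        assert pseudonym in report.flagged_patients
        assert manifest.patients[pseudonym].reference is None

    def test_unresolvable_patient_listed(self, cohort):
        df = pd.read_csv(cohort.cohort_csv, dtype=str)
        df.loc[0, "patient_id"] = "GHOST"
        k = make_key(df.patient_id.unique().tolist(), "s")
        _, report = build_manifest(df, cohort.source_store, k)
        assert "GHOST" in report.unresolved_patients

    def test_manifest_json_roundtrip(self, cohort, key, tmp_path):
        manifest, _ = build_manifest(cohort.cohort_csv, cohort.source_store, key)
        manifest.to_json(tmp_path / "m.json")
        back = CohortManifest.from_json(tmp_path / "m.json")
        assert back.patients.keys() == manifest.patients.keys()
        one = next(iter(manifest.patients))
        assert back.patients[one].reference.centroid == manifest.patients[one].reference.centroid


class TestExtraction:
    def test_pseudonymization_and_referential_integrity(self, cohort, key, tmp_path):
        pid = "PT0001"
        files = curation.extract_case(pid, cohort.source_store, key, tmp_path / "ext")
        assert files
        pseudonym = key.pseudonym(pid)
        for f in files:
            ds = pydicom.dcmread(f)
            assert str(ds.PatientID) == pseudonym
            assert pid not in str(ds.PatientName)
            for elem in ds.iterall():
                assert pid not in str(elem.value), elem
        assert curation.referential_integrity(tmp_path / "ext" / pseudonym)

    def test_extraction_is_deterministic(self, cohort, key, tmp_path):
        f1 = curation.extract_case("PT0002", cohort.source_store, key, tmp_path / "e1")
        f2 = curation.extract_case("PT0002", cohort.source_store, key, tmp_path / "e2")
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_locked_file_skipped(self, cohort, key, tmp_path):
        import json

        lock = cohort.source_store / "PT0003" / curation.EXTRACTION_LOCKS_FILE
        lock.write_text(json.dumps(["rp_0.dcm"]))
        try:
            files = curation.extract_case("PT0003", cohort.source_store, key, tmp_path / "ext")
            assert not any("rp_0" in f.name for f in files)
        finally:
            lock.unlink()


@pytest.fixture
def nomenclature():
    return NomenclatureMap(
        rules=[("Oesophagus.*", "Esophagus"), ("HEART", "Heart"), ("PBT", "Bronchus_Prox")]
    )


class TestNomenclature:
    @pytest.mark.parametrize(
        "alias,expected",
        [
            ("Oesophagus_L", "Esophagus"),
            ("heart", "Heart"),
            ("  p_b_t ", "Bronchus_Prox"),  # whitespace/underscore-normalized match
            ("PBT", "Bronchus_Prox"),
            ("pbt", "Bronchus_Prox"),
            ("Lung_R", None),
        ],
    )
    def test_alias_mapping(self, nomenclature, alias, expected):
        assert nomenclature.map_name(alias) == expected

    def test_first_match_wins(self):
        m = NomenclatureMap(rules=[("X.*", "First"), ("XY", "Second")])
        assert m.map_name("XY") == "Second"  # exact normalized match first
        assert m.map_name("XZ") == "First"


class TestCleanup:
    def _entry(self, manifest, pseudonym):
        return manifest.patients[pseudonym]

    def test_fraction_rescale_and_statuses(self, tmp_path, nomenclature):
        spec = phantom.PhantomSpec(
            patient_id="PTC", shape=(32, 32, 16), spacing=(5.0, 5.0, 5.0), body_radius=60.0,
            planned_fractions=33, delivered_fractions=30,
            dose_model={"kind": "uniform", "dose": 66.0},
            organ_names={"Bronchus_Prox": "PBT", "Heart": "HEART", "Esophagus": "Oesophagus_L"},
        )
        case = phantom.make_case(spec, tmp_path / "src")
        df = pd.DataFrame(
            [{"patient_id": "PTC", "course_id": "C9", "plan_id": spec.plan_id,
              "delivered_fractions": 30, "reference_structure_name": "BODY", "sex": "M"}]
        )
        k = make_key(["PTC"], "s")
        manifest, _ = build_manifest(df, tmp_path / "src", k)
        entry = manifest.patients[k.pseudonym("PTC")]

        result = cleanup_case(case, entry, nomenclature)
        assert result.flags == []
        out = result.case
        # 66 Gy * 30/33 = 60 Gy everywhere
        np.testing.assert_allclose(out.doses["C9:P1"].values, 60.0, rtol=1e-9)
        assert out.plan.plan_id == "C9:P1"
        assert out.plan.planned_fractions == 30 == out.plan.delivered_fractions
        assert out.plan.approval_status == "unapproved"
        assert out.plan.linked_plan_ids == []
        assert out.structure_set.approval_status == "unapproved"
        names = {s.name for s in out.structure_set.structures}
        assert {"Bronchus_Prox", "Heart", "Esophagus", "BODY"} <= names

    def test_idempotent(self, tmp_path, nomenclature):
        spec = phantom.PhantomSpec(
            patient_id="PTD", shape=(32, 32, 16), spacing=(5.0, 5.0, 5.0), body_radius=60.0,
            planned_fractions=20, delivered_fractions=18,
            organ_names={"Bronchus_Prox": "PBT", "Heart": "HEART", "Esophagus": "Oesophagus_L"},
        )
        case = phantom.make_case(spec, tmp_path / "src")
        df = pd.DataFrame(
            [{"patient_id": "PTD", "course_id": "C1", "plan_id": spec.plan_id,
              "delivered_fractions": 18, "reference_structure_name": "BODY", "sex": "F"}]
        )
        k = make_key(["PTD"], "s")
        manifest, _ = build_manifest(df, tmp_path / "src", k)
        entry = manifest.patients[k.pseudonym("PTD")]

        once = cleanup_case(case, entry, nomenclature).case
        twice = cleanup_case(once, entry, nomenclature).case
        assert once.plans == twice.plans
        np.testing.assert_array_equal(
            once.doses["C1:P1"].values, twice.doses["C1:P1"].values
        )

    def test_delivered_equals_planned_keeps_dose(self, default_case, nomenclature):
        import dataclasses

        from rtcohort.cohort_setup import PatientEntry, PlanEntry

        entry = PatientEntry(
            pseudonym="X", course_id="C2", sex="M",
            plans=[PlanEntry(default_case.plan.plan_id, 33, 33, 66.0)],
            expected_file_counts={}, reference=None,
        )
        nm = dataclasses.replace(
            nomenclature,
            rules=nomenclature.rules + [("Bronchus_Prox", "Bronchus_Prox"),
                                        ("Heart", "Heart"), ("Esophagus", "Esophagus")],
        )
        result = cleanup_case(default_case, entry, nm)
        np.testing.assert_array_equal(
            result.case.doses["C2:P1"].values, default_case.dose.values
        )
        assert result.case.plan.approval_status == "unapproved"

    def test_unmapped_organ_flags(self, default_case, nomenclature):
        from rtcohort.cohort_setup import PatientEntry, PlanEntry

        entry = PatientEntry(
            pseudonym="X", course_id="C3", sex="M",
            plans=[PlanEntry(default_case.plan.plan_id, 33, 33, 66.0)],
            expected_file_counts={}, reference=None,
        )
        result = cleanup_case(default_case, entry, nomenclature)
        assert any("unmapped organ" in f for f in result.flags)

    def test_zero_delivered_fractions_zeroes_and_flags(self, default_case, nomenclature):
        from rtcohort.cohort_setup import PatientEntry, PlanEntry

        entry = PatientEntry(
            pseudonym="X", course_id="C4", sex="M",
            plans=[PlanEntry(default_case.plan.plan_id, 33, 0, 66.0)],
            expected_file_counts={}, reference=None,
        )
        result = cleanup_case(default_case, entry, nomenclature)
        assert any("zero delivered" in f for f in result.flags)
        np.testing.assert_array_equal(result.case.doses["C4:P1"].values, 0.0)


class TestInjection:
    def test_idempotent_and_two_patients(self, cohort, key, tmp_path):
        e1 = curation.extract_case("PT0001", cohort.source_store, key, tmp_path / "ext")
        e2 = curation.extract_case("PT0002", cohort.source_store, key, tmp_path / "ext")
        store = tmp_path / "store"
        r1 = inject_case(e1, store)
        assert len(r1.written) == len(e1)
        r1b = inject_case(e1, store)
        assert not r1b.written and len(r1b.skipped_duplicates) == len(e1)
        inject_case(e2, store)
        assert len(list(store.iterdir())) == 2  # two patient roots

    def test_corrupted_file_rejected_by_name(self, tmp_path):
        bad = tmp_path / "garbage.dcm"
        bad.write_bytes(b"not dicom at all")
        with pytest.raises(CurationError, match="garbage.dcm"):
            inject_case([bad], tmp_path / "store")

    def test_same_id_different_content_collides(self, cohort, key, tmp_path):
        files = curation.extract_case("PT0001", cohort.source_store, key, tmp_path / "ext")
        store = tmp_path / "store"
        inject_case(files, store)
        ds = pydicom.dcmread(files[0])
        ds.add_new(0x00081030, "LO", "modified study")  # same SOP UID, new content
        ds.save_as(files[0], enforce_file_format=True)
        with pytest.raises(CurationError, match="collision"):
            inject_case([files[0]], store)
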