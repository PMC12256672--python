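"""The three QC processes: extraction counts, store integrity, volume flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from rtcohort import curation, phantom, qc, workflow
from rtcohort.cohort_setup import build_manifest, make_key
from rtcohort.curation import NomenclatureMap
from rtcohort.qc import FLAG, NOT_EVALUABLE, PASS, QCConfig, fit_volume_stats, qc_autoseg
from rtcohort.rt_model import ValidationError


@pytest.fixture(scope="module")
def pipeline(tmp_path_factory):
    """A small clean cohort carried through extraction -> research store."""
    out = tmp_path_factory.mktemp("qc_cohort")
    paths = phantom.make_cohort(3, out, seed=11)
    cohort = pd.read_csv(paths.cohort_csv, dtype=str)
    key = make_key(cohort.patient_id.unique().tolist(), "qc-salt")
    manifest, _ = build_manifest(paths.cohort_csv, paths.source_store, key)
    nomenclature = NomenclatureMap.from_csv(paths.nomenclature_csv)
    extracted = out / "extracted"
    research = out / "research"
    for pid in cohort.patient_id.unique():
        curation.extract_case(pid, paths.source_store, key, extracted)
    from rtcohort.rt_model import read_case, write_case

    cleaned = out / "cleaned"
    for pseudonym, entry in manifest.patients.items():
        result = curation.cleanup_case(read_case(extracted / pseudonym), entry, nomenclature)
        assert result.flags == []
        write_case(result.case, cleaned / pseudonym)
        curation.inject_case(sorted((cleaned / pseudonym).glob("*.dcm")), research)
    return {
        "paths": paths, "key": key, "manifest": manifest, "nomenclature": nomenclature,
        "extracted": extracted, "cleaned": cleaned, "research": research, "out": out,
    }


class TestQCExtraction:
    def test_clean_cohort_zero_flags(self, pipeline):
        report = qc.qc_extraction(pipeline["manifest"], pipeline["extracted"])
        assert report.n_flags == 0

    def test_missing_plan_file_flagged_with_modality(self, pipeline, tmp_path):
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(pipeline["extracted"], broken)
        victim = next(iter(pipeline["manifest"].patients))
        (broken / victim / "rp_0.dcm").unlink()
        report = qc.qc_extraction(pipeline["manifest"], broken)
        assert report.flagged_patients() == {victim}
        assert any(f.check_id == "file_count_RTPLAN" and "missing" in f.message
                   for f in report.flags)

    def test_surplus_dose_file_flagged(self, pipeline, tmp_path):
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(pipeline["extracted"], broken)
        victim = next(iter(pipeline["manifest"].patients))
        shutil.copy(broken / victim / "rd_0.dcm", broken / victim / "rd_extra.dcm")
        report = qc.qc_extraction(pipeline["manifest"], broken)
        assert any(f.check_id == "file_count_RTDOSE" and "surplus" in f.message
                   for f in report.flags)


class TestQCCleanupInjection:
    def test_clean_cohort_all_pass(self, pipeline):
        report = qc.qc_cleanup_injection(
            pipeline["manifest"], pipeline["research"], QCConfig(), pipeline["nomenclature"]
        )
        assert report.n_flags == 0
        assert {f.patient for f in report.findings} == set(pipeline["manifest"].patients)

    def test_dose_offset_above_tolerance_flags(self, pipeline, tmp_path):
        import shutil

        broken = tmp_path / "research"
        shutil.copytree(pipeline["research"], broken)
        victim = next(iter(pipeline["manifest"].patients))
        entry = {"kind": "dose_offset", "magnitude": 0.2}
        rd = next(p for p in (broken / victim).glob("rtdose_*.dcm"))
        rd.rename(broken / victim / "rd_0.dcm")
        phantom.apply_post_cleanup_fault(entry, broken / victim, None)
        report = qc.qc_cleanup_injection(
            pipeline["manifest"], broken, QCConfig(), pipeline["nomenclature"]
        )
        flagged = [f for f in report.flags if f.check_id == "reference_dose"]
        # 0.2 Gy offset > 0.1 Gy tolerance
        assert [f.patient for f in flagged] == [victim]

    def test_small_dose_offset_passes(self, pipeline, tmp_path):
        import shutil

        broken = tmp_path / "research"
        shutil.copytree(pipeline["research"], broken)
        victim = next(iter(pipeline["manifest"].patients))
        rd = next(p for p in (broken / victim).glob("rtdose_*.dcm"))
        rd.rename(broken / victim / "rd_0.dcm")
        phantom.apply_post_cleanup_fault(
            {"kind": "dose_offset", "magnitude": 0.05}, broken / victim, None
        )
        report = qc.qc_cleanup_injection(
            pipeline["manifest"], broken, QCConfig(), pipeline["nomenclature"]
        )
        assert not [f for f in report.flags if f.check_id == "reference_dose"]

    def test_structure_shift_beyond_tolerance_flags(self, pipeline, tmp_path):
        import shutil

        broken = tmp_path / "research"
        shutil.copytree(pipeline["research"], broken)
        victim = next(iter(pipeline["manifest"].patients))
        rs = next(p for p in (broken / victim).glob("rtstruct_*.dcm"))
        rs.rename(broken / victim / "rs_0.dcm")
        phantom.apply_post_cleanup_fault(
            {"kind": "structure_shift", "magnitude": 1.0}, broken / victim, None
        )
        report = qc.qc_cleanup_injection(
            pipeline["manifest"], broken, QCConfig(), pipeline["nomenclature"]
        )
        assert any(f.check_id == "reference_centroid" and f.patient == victim
                   for f in report.flags)


class TestVolumeStats:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame(
            {"organ": "Heart", "sex": "M", "volume_cm3": [10.0, 12.0, 14.0]}
        )
        stats = fit_volume_stats(df, min_training_n=3)
        s = stats.get("Heart", "M")
        assert s["mean"] == 12.0 and s["sd"] == pytest.approx(2.0)
        assert s["active"]

    def test_small_stratum_inactive(self):
        df = pd.DataFrame({"organ": "Heart", "sex": "F", "volume_cm3": np.arange(5.0) + 1})
        stats = fit_volume_stats(df, min_training_n=20)
        assert not stats.get("Heart", "F")["active"]

    def test_recovers_simulated_parameters(self):
        rng = np.random.default_rng(8)
        v = rng.normal(800.0, 100.0, 100)
        df = pd.DataFrame({"organ": "Heart", "sex": "M", "volume_cm3": v})
        s = fit_volume_stats(df).get("Heart", "M")
        assert s["mean"] == pytest.approx(800.0, abs=3 * 100.0 / 10.0)
        assert s["sd"] == pytest.approx(100.0, rel=0.3)

    def test_nonpositive_volumes_rejected(self):
        df = pd.DataFrame({"organ": "A", "sex": "M", "volume_cm3": [1.0, -2.0]})
        with pytest.raises(ValidationError):
            fit_volume_stats(df)


class TestQCAutoseg:
    def _stats(self):
        return qc.volume_stats_from_params({("Heart", "M"): (800.0, 80.0)})

    def _frame(self, volume):
        return pd.DataFrame(
            [{"patient": "RT0001", "organ": "Heart", "sex": "M", "volume_cm3": volume}]
        )

    @pytest.mark.parametrize(
        "offset_sd,expected",
        [(0.0, PASS), (2.99, PASS), (3.0, PASS), (3.01, FLAG), (-3.01, FLAG), (-2.99, PASS)],
    )
    def test_boundary_convention(self, offset_sd, expected):
        report = qc_autoseg(self._frame(800.0 + offset_sd * 80.0), self._stats(), QCConfig())
        assert report.findings[0].status == expected

    def test_missing_stratum_not_evaluable(self):
        frame = pd.DataFrame(
            [{"patient": "RT0001", "organ": "Liver", "sex": "M", "volume_cm3": 1000.0}]
        )
        report = qc_autoseg(frame, self._stats(), QCConfig())
        assert report.findings[0].status == NOT_EVALUABLE

    def test_flag_rate_matches_three_sigma_interval(self):
        """Volumes drawn from the fitted normal flag at ~ 2*Phi(-3) = 0.27%."""
        rng = np.random.default_rng(123)
        train = pd.DataFrame({"organ": "Heart", "sex": "M",
                              "volume_cm3": rng.normal(800, 80, 100)})
        stats = fit_volume_stats(train)
        s = stats.get("Heart", "M")
        n = 60_000
        draws = rng.normal(s["mean"], s["sd"], n)
        frame = pd.DataFrame({"patient": [f"P{i}" for i in range(n)], "organ": "Heart",
                              "sex": "M", "volume_cm3": draws})
        report = qc_autoseg(frame, stats, QCConfig())
        non_flag_rate = 1.0 - report.n_flags / n
        expected = 1.0 - 2.0 * scipy_stats.norm.sf(3.0)  # 0.99730
        assert non_flag_rate == pytest.approx(expected, abs=1e-3)
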