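"""Sequential cohort workflow: Setup through Collection.

``run_workflow`` executes the nine pipeline processes in order —
Setup, Extraction, QC of Extraction, Cleanup, AutoSeg, Injection,
QC of Cleanup & Injection, QC of AutoSeg, Collection — over every
patient in the cohort list, records per-process wall time and flag
counts, and defines success for a patient as "not flagged in any QC".

Autosegmentation is a pluggable backend behind a one-method contract
(CT in, StructureSet out, unattended over a whole cohort).  The built-in
``threshold`` backend is deliberately crude and deterministic: it
region-grows the airway from air voxels enclosed by the body, fits the
largest distinctly-attenuating soft-tissue blob with an ellipsoid for
the heart-like organ, and fits a posterior midline tube for the
esophagus-like organ.  It exists so the full pipeline runs without any
trained model; real deep-learning backends register through the same
interface.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from rtcohort import curation, dosimetry, geometry, qc, rt_model
from rtcohort.cohort_setup import (
    CohortManifest,
    build_manifest,
    make_key,
    read_cohort_list,
)
from rtcohort.curation import NomenclatureMap
from rtcohort.qc import QCConfig, QCReport, VolumeStats, fit_volume_stats
from rtcohort.rt_model import (
    AUTOSEG_LABEL,
    CTImageSeries,
    Grid3D,
    RTCase,
    RTModelError,
    Structure,
    StructureSet,
    ValidationError,
    read_case,
)

STANDARD_ORGANS = ("Bronchus_Prox", "Heart", "Esophagus")


class WorkflowError(ValidationError):
    pass


class NoBodyError(WorkflowError):
    """The threshold backend found no body in the CT."""


# ---------------------------------------------------------------------------
# autosegmentation backends
# ---------------------------------------------------------------------------

AutosegBackend = Callable[[CTImageSeries], StructureSet]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _mask_to_structure(mask: np.ndarray, grid: Grid3D, name: str) -> Structure:
    """Per-slice marching-squares contours of a voxel mask, in mm."""
    slices = []
    x0, y0, _ = grid.origin
    dx, dy, _ = grid.spacing
    for iz in range(grid.shape[2]):
        plane = mask[iz]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        polys = []
        for c in measure.find_contours(padded, 0.5):
            if np.allclose(c[0], c[-1]):
                c = c[:-1]
            if c.shape[0] < 3:
                continue
            polys.append(np.column_stack([x0 + dx * (c[:, 1] - 1), y0 + dy * (c[:, 0] - 1)]))
        if polys:
            slices.append((float(grid.z_centers[iz]), polys))
    return Structure(name, slices)


def _circle_poly(cx: float, cy: float, r: float, n: int = 32) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def threshold_backend(ct: CTImageSeries) -> StructureSet:
    """Reference backend: HU thresholding + simple shape fits.

    Airway: connected air not touching the lateral image borders (i.e.
    enclosed by the body).  Heart: ellipsoid fitted to the first and
    second moments of the brightest soft-tissue component.  Esophagus:
    per-slice circle fit (centroid + equivalent radius) of a mid-density
    posterior component.  Raises :class:`NoBodyError` on an all-air image.
    """
    hu = np.asarray(ct.values)
    grid = ct.grid
    body = _largest_component(hu > -400)
    if not body.any():
        raise NoBodyError("no body found in CT (image is all air)")

    # airway: air components enclosed laterally
    air_labels, n_air = ndimage.label(hu < -900)
    airway = np.zeros_like(body)
    for lab in range(1, n_air + 1):
        comp = air_labels == lab
        touches = (
            comp[:, 0, :].any() or comp[:, -1, :].any()
            or comp[:, :, 0].any() or comp[:, :, -1].any()
        )
        if not touches:
            airway |= comp
    structures = [_mask_to_structure(airway, grid, STANDARD_ORGANS[0])] if airway.any() else []

    heart_cc = _largest_component((hu >= 55) & (hu <= 85) & body)
    if heart_cc.any():
        pts = grid.voxel_centers(heart_cc)
        center = pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(pts.T))
        axes = np.sqrt(5.0 * np.clip(evals, 1e-9, None))
        X, Y = np.meshgrid(grid.x_centers, grid.y_centers)
        ellipsoid = np.zeros(grid.array_shape, bool)
        for iz, z in enumerate(grid.z_centers):
            d = np.stack([X - center[0], Y - center[1], np.full_like(X, z - center[2])], axis=-1)
            u = d @ evecs / axes
            ellipsoid[iz] = (u**2).sum(axis=-1) <= 1.0
        structures.append(_mask_to_structure(ellipsoid, grid, STANDARD_ORGANS[1]))

    eso_cc = _largest_component((hu >= 15) & (hu <= 35) & body)
    if eso_cc.any():
        slices = []
        voxel_area = grid.spacing[0] * grid.spacing[1]
        for iz in range(grid.shape[2]):
            plane = eso_cc[iz]
            n_vox = int(plane.sum())
            if n_vox == 0:
                continue
            iy, ix = np.nonzero(plane)
            cx = grid.origin[0] + grid.spacing[0] * ix.mean()
            cy = grid.origin[1] + grid.spacing[1] * iy.mean()
            r = float(np.sqrt(n_vox * voxel_area / np.pi))
            slices.append((float(grid.z_centers[iz]), [_circle_poly(cx, cy, r)]))
        if slices:
            structures.append(Structure(STANDARD_ORGANS[2], slices))

    return StructureSet(structures=structures, label=AUTOSEG_LABEL)


BACKENDS: dict[str, AutosegBackend] = {"threshold": threshold_backend}


def register_backend(name: str, backend: AutosegBackend) -> None:
    BACKENDS[name] = backend


# ---------------------------------------------------------------------------
# configuration / report
# ---------------------------------------------------------------------------


@dataclass
class WorkflowConfig:
    source_store: str
    cohort_csv: str
    nomenclature_csv: str
    work_dir: str
    salt: str = "rtcohort"
    backend: str = "threshold"
    qc_config: QCConfig = field(default_factory=QCConfig)
    organs: tuple[str, ...] = STANDARD_ORGANS
    metrics: tuple[str, ...] = ("d_mean",)
    volume_stats_json: str | None = None  # per-stratum mean/sd from training data
    fault_ledger: str | None = None  # truth ledger whose post-cleanup faults to simulate
    halt_on_flag: bool = False
    export_dvh: bool = False

    @property
    def extracted_store(self) -> Path:
        return Path(self.work_dir) / "extracted_store"

    @property
    def cleaned_store(self) -> Path:
        return Path(self.work_dir) / "cleaned_store"

    @property
    def research_store(self) -> Path:
        return Path(self.work_dir) / "research_store"

    @property
    def reports_dir(self) -> Path:
        return Path(self.work_dir) / "reports"

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "qc_config" in raw:
            raw["qc_config"] = QCConfig(**raw["qc_config"])
        for key in ("organs", "metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_flags: dict[str, int] = field(default_factory=dict)
    cleanup_flags: dict[str, list[str]] = field(default_factory=dict)
    success_by_patient: dict[str, bool] = field(default_factory=dict)
    halted_after: str | None = None

    @property
    def n_success(self) -> int:
        return sum(self.success_by_patient.values())

    @property
    def success_fraction(self) -> float:
        if not self.success_by_patient:
            return 0.0
        return self.n_success / len(self.success_by_patient)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# ---------------------------------------------------------------------------
# helper stages
# ---------------------------------------------------------------------------


def load_volume_stats(path: str | Path) -> VolumeStats:
    rows = json.loads(Path(path).read_text())
    return VolumeStats(
        strata={
            (r["organ"], r["sex"]): {
                "mean": r["mean"], "sd": r["sd"], "n": r.get("n", 0),
                "active": r.get("n", 0) >= 1,
            }
            for r in rows
        }
    )


def autoseg_volumes(
    manifest: CohortManifest, research_store: Path, organs: tuple[str, ...]
) -> pd.DataFrame:
    """Autosegmentation volumes (cm^3) per patient and organ."""
    rows = []
    for pseudonym, entry in manifest.patients.items():
        case_dir = research_store / pseudonym
        if not case_dir.is_dir():
            continue
        try:
            case = read_case(case_dir)
        except RTModelError:
            continue
        ss = case.get_structure_set(AUTOSEG_LABEL)
        if ss is None:
            continue
        for organ in organs:
            s = ss.find(organ)
            if s is None:
                continue
            mask = geometry.rasterize(s, case.ct.grid)
            rows.append(
                {"patient": pseudonym, "organ": organ, "sex": entry.sex,
                 "volume_cm3": geometry.volume_cm3(mask)}
            )
    return pd.DataFrame(rows, columns=["patient", "organ", "sex", "volume_cm3"])


def collect_metrics(
    manifest: CohortManifest,
    research_store: str | Path,
    metrics: tuple[str, ...] = ("d_mean",),
    organs: tuple[str, ...] = STANDARD_ORGANS,
    structure_label: str = AUTOSEG_LABEL,
    dvh_dir: str | Path | None = None,
) -> pd.DataFrame:
    """The Collection table: one row per patient, one column per
    (organ, metric); missing organs leave empty cells and a flag note."""
    research_store = Path(research_store)
    rows = []
    for pseudonym, entry in manifest.patients.items():
        row: dict = {"patient": pseudonym}
        flags = []
        case_dir = research_store / pseudonym
        if not case_dir.is_dir():
            rows.append(row | {"flags": "missing patient"})
            continue
        try:
            case = read_case(case_dir)
        except RTModelError as exc:
            rows.append(row | {"flags": f"unreadable: {exc}"})
            continue
        ss = case.get_structure_set(structure_label) or case.structure_set
        for organ in organs:
            s = ss.find(organ) if ss else None
            if s is None:
                flags.append(f"missing {organ}")
                for metric in metrics:
                    row[f"{organ}_{metric}"] = np.nan
                continue
            mask = geometry.rasterize(s, case.ct.grid)
            if mask.n_voxels == 0:
                flags.append(f"empty {organ}")
                for metric in metrics:
                    row[f"{organ}_{metric}"] = np.nan
                continue
            doses = np.zeros(0)
            total = None
            for dose in case.doses.values():
                d = dosimetry.voxel_doses(mask, dose)
                total = d if total is None else total + d
            doses = total if total is not None else np.zeros(0)
            for metric in metrics:
                if doses.size == 0:
                    row[f"{organ}_{metric}"] = np.nan
                    flags.append(f"no dose for {organ}")
                    continue
                if metric == "d_mean":
                    row[f"{organ}_{metric}"] = dosimetry.d_mean(doses)
                elif metric == "d_2pct":
                    row[f"{organ}_{metric}"] = dosimetry.d_percent(doses, 0.02)
                elif metric == "volume_cm3":
                    row[f"{organ}_{metric}"] = geometry.volume_cm3(mask)
                else:
                    raise WorkflowError(f"unknown collection metric {metric!r}")
            if dvh_dir is not None and doses.size:
                Path(dvh_dir).mkdir(parents=True, exist_ok=True)
                dosimetry.dvh_to_csv(
                    dosimetry.cumulative_dvh(doses, bin_width=0.1),
                    Path(dvh_dir) / f"{pseudonym}_{organ}_dvh.csv",
                )
        row["flags"] = "; ".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the workflow
# ---------------------------------------------------------------------------


def run_workflow(config: WorkflowConfig) -> RunReport:
    """Execute all pipeline processes sequentially over the cohort."""
    report = RunReport()
    reports_dir = config.reports_dir
    reports_dir.mkdir(parents=True, exist_ok=True)
    nomenclature = NomenclatureMap.from_csv(config.nomenclature_csv)
    backend = BACKENDS[config.backend]
    qc_cfg = config.qc_config

    def timed(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                report.stage_seconds[name] = round(time.perf_counter() - self_inner.t0, 3)

        return _Timer()

    # ---- Setup
    with timed("setup"):
        cohort = read_cohort_list(config.cohort_csv)
        key = make_key(sorted(cohort.patient_id.unique()), salt=config.salt)
        key.to_csv(reports_dir / "pseudonymization_key.csv")
        manifest, build_report = build_manifest(cohort, config.source_store, key)
        manifest.to_json(reports_dir / "manifest.json")
        report.stage_flags["setup"] = len(build_report.unresolved_patients) + len(
            build_report.flagged_patients
        )

    # ---- Extraction
    with timed("extraction"):
        for patient_id in sorted(cohort.patient_id.unique()):
            curation.extract_case(patient_id, config.source_store, key, config.extracted_store)

    # ---- QC of Extraction
    with timed("qc_extraction"):
        qc_extraction_report = qc.qc_extraction(manifest, config.extracted_store)
        qc_extraction_report.to_json(reports_dir / "qc_extraction.json")
        report.stage_flags["qc_extraction"] = qc_extraction_report.n_flags
    if config.halt_on_flag and qc_extraction_report.n_flags:
        report.halted_after = "qc_extraction"
        return report

    # ---- Cleanup
    with timed("cleanup"):
        for pseudonym, entry in manifest.patients.items():
            case = read_case(config.extracted_store / pseudonym)
            result = curation.cleanup_case(case, entry, nomenclature)
            if result.flags:
                report.cleanup_flags[pseudonym] = result.flags
            rt_model.write_case(result.case, config.cleaned_store / pseudonym)
        report.stage_flags["cleanup"] = len(report.cleanup_flags)

    # ---- AutoSeg
    with timed("autoseg"):
        for pseudonym in manifest.patients:
            case_dir = config.cleaned_store / pseudonym
            case = read_case(case_dir)
            auto = backend(case.ct)
            case.structure_sets = [
                ss for ss in case.structure_sets if ss.label != AUTOSEG_LABEL
            ] + [auto]
            rt_model.write_case(case, case_dir)

    # ---- simulated post-cleanup faults (validation harness)
    if config.fault_ledger:
        ledger = json.loads(Path(config.fault_ledger).read_text())
        from rtcohort.phantom import apply_post_cleanup_fault

        for entry in ledger.get("errors", []):
            if not entry.get("post_cleanup"):
                continue
            pseudonym = key.pseudonym(entry["patient_id"])
            ref = manifest.patients[pseudonym].reference
            apply_post_cleanup_fault(
                entry, config.cleaned_store / pseudonym,
                ref.centroid if ref else (0.0, 0.0, 0.0),
            )

    # ---- Injection
    with timed("injection"):
        for pseudonym in manifest.patients:
            files = sorted((config.cleaned_store / pseudonym).glob("*.dcm"))
            curation.inject_case(files, config.research_store)

    # ---- QC of Cleanup & Injection
    with timed("qc_cleanup_injection"):
        qc_inject_report = qc.qc_cleanup_injection(
            manifest, config.research_store, qc_cfg, nomenclature
        )
        qc_inject_report.to_json(reports_dir / "qc_cleanup_injection.json")
        report.stage_flags["qc_cleanup_injection"] = qc_inject_report.n_flags
    if config.halt_on_flag and qc_inject_report.n_flags:
        report.halted_after = "qc_cleanup_injection"
        return report

    # ---- QC of AutoSeg
    with timed("qc_autoseg"):
        if config.volume_stats_json:
            stats = load_volume_stats(config.volume_stats_json)
        else:
            manual = _manual_volumes(manifest, config.research_store, config.organs)
            stats = fit_volume_stats(manual, min_training_n=qc_cfg.min_training_n)
        volumes = autoseg_volumes(manifest, config.research_store, config.organs)
        qc_autoseg_report = qc.qc_autoseg(volumes, stats, qc_cfg)
        qc_autoseg_report.to_json(reports_dir / "qc_autoseg.json")
        report.stage_flags["qc_autoseg"] = qc_autoseg_report.n_flags

    # ---- Collection
    with timed("collection"):
        table = collect_metrics(
            manifest,
            config.research_store,
            metrics=config.metrics,
            organs=config.organs,
            dvh_dir=(reports_dir / "dvh") if config.export_dvh else None,
        )
        table.to_csv(reports_dir / "collection.csv", index=False)

    flagged = (
        qc_extraction_report.flagged_patients()
        | qc_inject_report.flagged_patients()
        | qc_autoseg_report.flagged_patients()
        | set(report.cleanup_flags)
    )
    for pseudonym in manifest.patients:
        report.success_by_patient[pseudonym] = pseudonym not in flagged
    report.to_json(reports_dir / "run_report.json")
    return report


def _manual_volumes(
    manifest: CohortManifest, research_store: Path, organs: tuple[str, ...]
) -> pd.DataFrame:
    """Volumes of the manually contoured organs (training-style stats)."""
    rows = []
    for pseudonym, entry in manifest.patients.items():
        case_dir = Path(research_store) / pseudonym
        if not case_dir.is_dir():
            continue
        try:
            case = read_case(case_dir)
        except RTModelError:
            continue
        if case.structure_set is None:
            continue
        for organ in organs:
            s = case.structure_set.find(organ)
            if s is None:
                continue
            mask = geometry.rasterize(s, case.ct.grid)
            if mask.n_voxels:
                rows.append(
                    {"patient": pseudonym, "organ": organ, "sex": entry.sex,
                     "volume_cm3": geometry.volume_cm3(mask)}
                )
    return pd.DataFrame(rows, columns=["patient", "organ", "sex", "volume_cm3"])
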