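"""End-to-end orchestration: images -> lesion metrics -> cohort statistics.

Per patient and timepoint, each available modality is quantified
independently (per-stage failure isolation: a corrupt PET input does
not discard the MRI metrics for that visit); missing modalities simply
leave their metric fields missing, so per-metric analysis Ns follow
from the data. Percent changes from baseline at mid and post feed the
statistics grid, and a run manifest records config hash, input
checksums, package version, and seeds so a rerun with the same manifest
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .core import (
    ALL_METRICS,
    DynamicPetSeries,
    ImageVolume,
    LesionMetrics,
    MpqError,
    PatientOutcome,
    PatientPhysiology,
    TimeActivityCurve,
)
from . import dce, dwi, pet
from .io import (
    file_sha256,
    metric_column,
    read_frame_timing,
    read_tac,
    read_volume,
    validate_cohort_table,
    write_cohort_table,
)
from .stats import AnalysisReport, mismatch_ratios, percent_change, run_full_analysis

log = logging.getLogger("mpq.pipeline")


@dataclass
class DceInputs:
    s0: ImageVolume
    s1: ImageVolume
    s2: ImageVolume
    seed_point: Optional[tuple[int, int, int]] = None


@dataclass
class DwiInputs:
    volumes: list[ImageVolume]
    b_values: list[float]
    roi_mask: Optional[np.ndarray] = None  # defaults to the DCE tumor mask


@dataclass
class PetInputs:
    series: DynamicPetSeries
    blood_tac: TimeActivityCurve
    voi_center: Optional[tuple[float, float, float]] = None  # default: SUV hotspot


@dataclass
class TimepointInputs:
    dce: Optional[DceInputs] = None
    dwi: Optional[DwiInputs] = None
    pet: Optional[PetInputs] = None


def quantify_patient(
    inputs: TimepointInputs,
    phys: Optional[PatientPhysiology],
    config: Optional[AnalysisConfig] = None,
    timepoint: str = "baseline",
) -> tuple[LesionMetrics, list[str]]:
    """Quantify one patient visit; returns metrics plus per-stage errors.

    Every modality is processed in isolation; a stage failure is logged
    and recorded, and the remaining modalities still produce metrics.
    Raises only when no modality is present at all.
    """
    config = config or AnalysisConfig()
    if inputs.dce is None and inputs.dwi is None and inputs.pet is None:
        raise MpqError("no usable modality for this visit")
    m = LesionMetrics(timepoint=timepoint)
    errors: list[str] = []

    tumor_mask = None
    if inputs.dce is not None:
        try:
            pe_map = dce.compute_pe_map(inputs.dce.s0, inputs.dce.s1)
            ser_map = dce.compute_ser_map(
                inputs.dce.s0, inputs.dce.s1, inputs.dce.s2, epsilon=config.ser_epsilon
            )
            tumor_mask = dce.segment_tumor(
                pe_map, threshold=config.pe_threshold, seed_point=inputs.dce.seed_point
            )
            if tumor_mask.empty:
                errors.append("dce: no enhancing lesion")
            else:
                m.peak_pe = dce.hotspot_peak(pe_map, tumor_mask, config.hotspot_window)
                m.peak_ser = dce.hotspot_peak(ser_map, tumor_mask, config.hotspot_window)
                m.ftv = dce.functional_tumor_volume(pe_map, tumor_mask, config.pe_threshold)
                m.washout_volume = dce.washout_volume(
                    ser_map, tumor_mask, config.ser_threshold
                )
                m.longest_dimension = dce.longest_dimension(tumor_mask)
        except MpqError as exc:
            errors.append(f"dce: {exc}")
            log.warning("DCE stage failed: %s", exc)

    if inputs.dwi is not None:
        try:
            fit = dwi.fit_adc(inputs.dwi.volumes, inputs.dwi.b_values, method=config.adc_fit)
            roi = inputs.dwi.roi_mask
            if roi is None:
                if tumor_mask is None or tumor_mask.empty:
                    raise MpqError("no ROI supplied and no DCE tumor mask available")
                roi = tumor_mask
            else:
                roi = dce.TumorMask(np.asarray(roi, bool), inputs.dwi.volumes[0].spacing)
            mean_adc, _ = dwi.roi_mean_adc(fit, roi)
            m.mean_adc = mean_adc * 1000.0  # report in 1e-3 mm^2/s units
        except MpqError as exc:
            errors.append(f"dwi: {exc}")
            log.warning("DWI stage failed: %s", exc)

    if inputs.pet is not None:
        try:
            if phys is None:
                raise MpqError("PET quantification requires patient physiology")
            suv_img = pet.summed_suv_image(inputs.pet.series, phys, config.suv_window)
            center = inputs.pet.voi_center
            if center is None:
                center = pet.locate_lesion_center(suv_img)
            m.suvmax = pet.suvmax_in_voi(suv_img, tuple(center), config.voi_volume_cc)
            voi = pet.sphere_voi_mask(suv_img, tuple(center), config.voi_volume_cc)
            tac = pet.extract_tac(inputs.pet.series, voi)
            fit = pet.fit_two_tissue(
                tac,
                inputs.pet.blood_tac,
                frame_start=inputs.pet.series.frame_start,
                frame_end=inputs.pet.series.frame_end,
                fit_vb=config.fit_vb,
                k_upper=config.k_upper,
                dt=config.conv_dt_min,
            )
            if fit.success:
                m.k1, m.k2, m.k3 = fit.params.k1, fit.params.k2, fit.params.k3
                m.ki = fit.ki
                if phys.plasma_glucose is not None:
                    m.mrfdg = pet.metabolic_rate_fdg(
                        fit.params, phys, expected_glucose_unit=config.glucose_unit
                    )
            else:
                errors.append(f"pet: kinetic fit failed ({fit.message})")
        except MpqError as exc:
            errors.append(f"pet: {exc}")
            log.warning("PET stage failed: %s", exc)

    mismatch_ratios(m)
    m.check_invariants()
    return m, errors


# ----------------------------------------------------------------- study runs


def _load_timepoint(spec: dict, base: Path) -> TimepointInputs:
    """Build TimepointInputs from one manifest timepoint entry."""
    tp = TimepointInputs()
    if "dce" in spec:
        d = spec["dce"]
        tp.dce = DceInputs(
            s0=read_volume(base / d["s0"]),
            s1=read_volume(base / d["s1"]),
            s2=read_volume(base / d["s2"]),
            seed_point=tuple(d["seed_point"]) if "seed_point" in d else None,
        )
    if "dwi" in spec:
        d = spec["dwi"]
        roi = None
        if "roi" in d:
            roi = read_volume(base / d["roi"]).voxels > 0.5
        tp.dwi = DwiInputs(
            volumes=[read_volume(base / p) for p in d["volumes"]],
            b_values=[float(b) for b in d["b_values"]],
            roi_mask=roi,
        )
    if "pet" in spec:
        d = spec["pet"]
        start, end = read_frame_timing(base / d["timing"])
        frames = [read_volume(base / p) for p in d["frames"]]
        tp.pet = PetInputs(
            series=DynamicPetSeries(frames, start, end),
            blood_tac=read_tac(base / d["blood_tac"], label="blood"),
            voi_center=tuple(d["voi_center"]) if "voi_center" in d else None,
        )
    return tp


def _manifest_files(manifest: dict) -> list[str]:
    files: list[str] = []

    def walk(node):
        if isinstance(node, dict):
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)
        elif isinstance(node, str) and any(
            node.endswith(ext) for ext in (".nii", ".nii.gz", ".csv")
        ):
            files.append(node)

    walk(manifest)
    return sorted(set(files))


def run_study(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: Optional[AnalysisConfig] = None,
) -> tuple[AnalysisReport, dict]:
    """Run the full study described by a YAML manifest.

    Per patient: quantify every listed timepoint, derive percent changes
    and mismatch ratios, then run the cohort statistics grid. Schema or
    stage errors are recorded per patient and the run continues. All
    outputs are CSV with pinned float formatting; the returned manifest
    dict is also written as JSON for provenance.
    """
    config = config or AnalysisConfig()
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    if not manifest or not manifest.get("patients"):
        raise MpqError("no patients in manifest")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t_start = time.time()
    metric_rows = []
    cohort_rows = []
    error_ledger: dict[str, list[str]] = {}
    for p in manifest["patients"]:
        pid = str(p["id"])
        errs: list[str] = []
        try:
            phys = PatientPhysiology(**p["physiology"]) if "physiology" in p else None
            outcome = PatientOutcome(**p["outcome"])
        except (MpqError, KeyError, TypeError) as exc:
            error_ledger[pid] = [f"schema: {exc}"]
            log.error("patient %s skipped: %s", pid, exc)
            continue
        per_tp: dict[str, LesionMetrics] = {}
        for tp_name, tp_spec in p.get("timepoints", {}).items():
            try:
                tp_inputs = _load_timepoint(tp_spec, base)
                metrics, tp_errs = quantify_patient(tp_inputs, phys, config, tp_name)
                per_tp[tp_name] = metrics
                errs.extend(f"{tp_name}/{e}" for e in tp_errs)
            except (MpqError, KeyError, OSError) as exc:
                errs.append(f"{tp_name}: {exc}")
                log.error("patient %s %s failed: %s", pid, tp_name, exc)
        for tp_name, metrics in per_tp.items():
            row = {"patient_id": pid, **metrics.as_dict()}
            metric_rows.append(row)

        cohort_row: dict = {
            "patient_id": pid,
            "rcb_class": outcome.rcb_class.value,
            "rfs_time_years": outcome.rfs_time_years,
            "rfs_event": outcome.rfs_event,
        }
        baseline = per_tp.get("baseline")
        for metric in ALL_METRICS:
            if baseline is not None:
                cohort_row[metric_column(metric, "baseline")] = getattr(baseline, metric)
            for tp_name in ("mid", "post"):
                follow = per_tp.get(tp_name)
                change = None
                if baseline is not None and follow is not None:
                    change = percent_change(
                        getattr(baseline, metric), getattr(follow, metric)
                    )
                cohort_row[metric_column(metric, tp_name)] = change
        cohort_rows.append(cohort_row)
        if errs:
            error_ledger[pid] = errs

    if not cohort_rows:
        raise MpqError("no patients could be quantified")
    cohort = validate_cohort_table(pd.DataFrame(cohort_rows))
    report = run_full_analysis(cohort, config)

    # ------------------------------------------------------------- outputs
    fmt = "%.10g"
    pd.DataFrame(metric_rows).to_csv(out_dir / "lesion_metrics.csv", index=False, float_format=fmt)
    write_cohort_table(cohort, out_dir / "cohort.csv")
    report.results_frame().to_csv(out_dir / "stat_results.csv", index=False, float_format=fmt)
    report.group_summary.to_csv(out_dir / "group_summary.csv", index=False, float_format=fmt)
    report.cox_summary.to_csv(out_dir / "cox_summary.csv", index=False, float_format=fmt)
    report.spearman_baseline.to_csv(out_dir / "spearman_baseline.csv", index=False, float_format=fmt)
    km_frames = [
        pd.concat([k.curve_larger_decrease, k.curve_smaller_decrease]).assign(metric=m)
        for m, k in report.km.items()
        if k.curve_larger_decrease is not None
    ]
    km_df = pd.concat(km_frames) if km_frames else pd.DataFrame(
        columns=["time_years", "survival", "group", "metric"]
    )
    km_df.to_csv(out_dir / "km_curves.csv", index=False, float_format=fmt)

    config_yaml = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    run_manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "manifest_file": str(manifest_path),
        "input_checksums": {
            f: file_sha256(base / f) for f in _manifest_files(manifest)
            if (base / f).exists()
        },
        "seeds": manifest.get("seeds", {}),
        "n_patients": len(cohort_rows),
        "errors": error_ledger,
        "stage_seconds": round(time.time() - t_start, 3),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return report, run_manifest
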