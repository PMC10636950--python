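"""Volume, time-activity-curve, and cohort-table I/O.

Volumes are exchanged as NIfTI-1 (via nibabel); on read, the array is
normalized to the package's (slice, row, col) order with matching
spacing. Tabular data are plain CSV. Missing metric cells are retained
as missing markers, never dropped — per-metric analysis Ns follow from
missingness.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    ALL_METRICS,
    ImageVolume,
    MpqError,
    RcbClass,
    TimeActivityCurve,
)

log = logging.getLogger("mpq")

# Wide cohort-table schema: one row per patient.
OUTCOME_COLUMNS = ("patient_id", "rcb_class", "rfs_time_years", "rfs_event")
VALID_RCB_LABELS = {c.value for c in RcbClass}


def metric_column(metric: str, timepoint: str) -> str:
    """Column name for a metric value or percent change in the cohort table."""
    if timepoint == "baseline":
        return f"{metric}_baseline"
    return f"pct_{metric}_{timepoint}"


def read_volume(path: str | Path, expected_axes: str = "zyx") -> ImageVolume:
    """Read a NIfTI-1 volume into the package's (slice, row, col) order.

    NIfTI stores fastest-varying axis first (i, j, k); the in-memory
    convention here is the reverse, so the payload is transposed and the
    spacing reordered to match.
    """
    path = Path(path)
    if not path.exists():
        raise MpqError(f"missing file: {path}")
    if expected_axes != "zyx":
        raise MpqError(f"unsupported axis convention {expected_axes!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MpqError(f"non-3D payload in {path}: shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MpqError(f"non-positive spacing in {path}: {zooms}")
    return ImageVolume(
        voxels=np.transpose(data, (2, 1, 0)).astype(float),
        spacing=tuple(float(z) for z in zooms[::-1]),
    )


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 (float64 payload)."""
    affine = np.diag(list(volume.spacing[::-1]) + [1.0])
    data = np.transpose(volume.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing[::-1])
    nib.save(img, str(path))


def read_tac(path: str | Path, label: str = "tumor") -> TimeActivityCurve:
    """Read a TAC CSV with columns ``midtime_min, activity_kbq_ml``."""
    df = pd.read_csv(path)
    for col in ("midtime_min", "activity_kbq_ml"):
        if col not in df.columns:
            raise MpqError(f"TAC file {path} lacks required column {col!r}")
    return TimeActivityCurve(
        midtimes=df["midtime_min"].to_numpy(float),
        activity=df["activity_kbq_ml"].to_numpy(float),
        label=label,
    )


def write_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"midtime_min": tac.midtimes, "activity_kbq_ml": tac.activity}
    ).to_csv(path, index=False)


def read_frame_timing(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read PET frame timing CSV with columns ``start_min, end_min``."""
    df = pd.read_csv(path)
    for col in ("start_min", "end_min"):
        if col not in df.columns:
            raise MpqError(f"frame timing file {path} lacks column {col!r}")
    return df["start_min"].to_numpy(float), df["end_min"].to_numpy(float)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate outcome columns and normalize dtypes; keep missing cells."""
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise MpqError(f"cohort table lacks required columns: {missing}")
    df = df.copy()
    labels = df["rcb_class"].astype(str).str.strip()
    bad = sorted(set(labels) - VALID_RCB_LABELS)
    if bad:
        raise MpqError(f"unknown RCB labels: {bad}")
    df["rcb_class"] = labels
    df["rfs_time_years"] = df["rfs_time_years"].astype(float)
    if (df["rfs_time_years"] <= 0).any():
        raise MpqError("rfs_time must be strictly positive for every patient")
    df["rfs_event"] = df["rfs_event"].astype(int).astype(bool)
    df["responder"] = [RcbClass(lbl).responder for lbl in df["rcb_class"]]
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV.

    Rows with missing metric cells are retained with NaN markers so the
    per-metric N of each downstream test reflects true missingness.
    """
    path = Path(path)
    if not path.exists():
        raise MpqError(f"missing file: {path}")
    return validate_cohort_table(pd.read_csv(path))


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["rfs_event"] = out["rfs_event"].astype(int)
    # Pinned float format keeps reruns bit-identical.
    out.to_csv(path, index=False, float_format="%.10g")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def setup_logging(level: int = logging.INFO) -> None:
    """Structured-ish stage logging: ``time | stage | message``."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s | %(name)s | %(levelname)s | %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level)
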