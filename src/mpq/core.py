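"""Shared data model for multimodal PET/MRI tumor quantification.

Conventions used throughout the package:

* Image volumes are indexed ``(slice, row, col)`` — the slice axis is the
  through-plane (axial) direction; all "3 x 3" neighborhoods are in-plane.
* Physical spacing is millimetres per axis; volumes are cubic millimetres
  internally and reported in cc (1 cc = 1000 mm^3).
* PET frame times are minutes post injection, activities kBq/mL.
* Kinetic rate constants: K1 in mL/min/g, k2 and k3 in 1/min; the net flux
  Ki = K1*k3/(k2+k3) is always recomputed from the micro-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional, Sequence

import numpy as np

AXIS_ORDER = "zyx"  # (slice, row, col)


class MpqError(Exception):
    """Base error for invalid inputs to the quantification pipeline."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array, arbitrary units. NaN is allowed only to mark voxels
        that are explicitly invalid (e.g. masked SER voxels).
    spacing
        Per-axis physical voxel size in mm, ordered like the array axes.
    axes
        Axis-order tag; the package convention is ``"zyx"``
        (slice, row, col).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axes: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise MpqError(f"non-3D payload: got {self.voxels.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MpqError(f"spacing must be three positive values, got {self.spacing}")
        if self.axes != AXIS_ORDER:
            raise MpqError(f"unsupported axis order {self.axes!r}; expected {AXIS_ORDER!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "ImageVolume", rtol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=rtol
        )


def require_same_grid(*volumes: ImageVolume) -> None:
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid(v):
            raise MpqError(
                f"grid mismatch: {ref.shape}/{ref.spacing} vs {v.shape}/{v.spacing}"
            )


@dataclass
class DynamicPetSeries:
    """An ordered dynamic PET acquisition (decay-corrected activity frames)."""

    frames: list[ImageVolume]
    frame_start: np.ndarray  # minutes post injection
    frame_end: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_end = np.asarray(self.frame_end, dtype=float)
        n = len(self.frames)
        if self.frame_start.shape != (n,) or self.frame_end.shape != (n,):
            raise MpqError("frame timing arrays must match the number of frames")
        if n == 0:
            raise MpqError("dynamic series must contain at least one frame")
        if np.any(self.frame_end <= self.frame_start):
            raise MpqError("frame_end must exceed frame_start for every frame")
        if np.any(np.diff(self.frame_start) <= 0) or np.any(
            self.frame_start[1:] < self.frame_end[:-1] - 1e-9
        ):
            raise MpqError("frames must be strictly ordered and non-overlapping")
        require_same_grid(*self.frames)

    @property
    def midtimes(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class TimeActivityCurve:
    """Activity (kBq/mL) versus frame midtime (minutes) for one region."""

    midtimes: np.ndarray
    activity: np.ndarray
    label: str = "tumor"  # "tumor" or "blood"

    def __post_init__(self) -> None:
        self.midtimes = np.asarray(self.midtimes, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.midtimes.ndim != 1 or self.midtimes.shape != self.activity.shape:
            raise MpqError("midtimes and activity must be 1D arrays of equal length")
        if self.midtimes.size == 0:
            raise MpqError("empty time grid")
        if self.midtimes.size > 1 and np.any(np.diff(self.midtimes) <= 0):
            raise MpqError("midtimes must be strictly increasing")

    def clipped(self) -> "TimeActivityCurve":
        """Return a copy with negative (noise) activities clipped to zero.

        Clipping is an explicit, caller-requested operation; curves are
        never silently clipped on construction.
        """
        return TimeActivityCurve(self.midtimes.copy(), np.clip(self.activity, 0, None), self.label)


@dataclass
class PatientPhysiology:
    """Per-study physiological inputs for SUV and MRFDG computation."""

    injected_dose_mbq: float
    body_weight_kg: float
    plasma_glucose: Optional[float] = None
    glucose_unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0 or self.body_weight_kg <= 0:
            raise MpqError("injected dose and body weight must be strictly positive")
        if self.plasma_glucose is not None and self.plasma_glucose <= 0:
            raise MpqError("plasma glucose must be strictly positive when provided")


class RcbClass(str, Enum):
    """Residual cancer burden class after neoadjuvant chemotherapy.

    Patients who progressed to metastatic disease before surgery carry a
    dedicated label and are grouped with RCB II/III (non-responders).
    """

    RCB_0 = "0"
    RCB_I = "I"
    RCB_II = "II"
    RCB_III = "III"
    METASTASIS_PRE_SURGERY = "metastasis_pre_surgery"

    @property
    def responder(self) -> bool:
        return self in (RcbClass.RCB_0, RcbClass.RCB_I)


@dataclass
class PatientOutcome:
    """Pathological response and recurrence-free survival for one patient."""

    rcb_class: RcbClass
    rfs_time_years: float
    rfs_event: bool

    def __post_init__(self) -> None:
        self.rcb_class = RcbClass(self.rcb_class)
        if self.rfs_time_years <= 0:
            raise MpqError(f"rfs_time must be positive, got {self.rfs_time_years}")
        self.rfs_event = bool(self.rfs_event)

    @property
    def responder(self) -> bool:
        return self.rcb_class.responder


TIMEPOINTS = ("baseline", "mid", "post")

# Canonical metric names, in the order the summary tables print them.
PET_METRICS = ("k1", "mrfdg", "suvmax")
MRI_METRICS = (
    "adc",
    "peak_pe",
    "peak_ser",
    "ftv",
    "washout_volume",
    "longest_dimension",
)
RATIO_METRICS = (
    "mrfdg_peak_pe",
    "mrfdg_peak_ser",
    "mrfdg_k1",
    "suvmax_peak_pe",
    "suvmax_peak_ser",
)
ALL_METRICS = PET_METRICS + MRI_METRICS + RATIO_METRICS


@dataclass
class LesionMetrics:
    """All quantitative measures for one lesion at one timepoint.

    Fields left ``None`` are missing (e.g. the modality was not acquired);
    downstream analyses keep per-metric Ns accordingly, no imputation.

    Units: peak_pe and peak_ser dimensionless; ftv and washout_volume cc;
    longest_dimension mm; mean_adc 1e-3 mm^2/s; suvmax dimensionless
    (tissue density 1 g/mL); k1 and ki mL/min/g; k2, k3 1/min; mrfdg in
    Ki units times the declared glucose concentration unit.
    """

    timepoint: str = "baseline"
    peak_pe: Optional[float] = None
    peak_ser: Optional[float] = None
    ftv: Optional[float] = None
    washout_volume: Optional[float] = None
    longest_dimension: Optional[float] = None
    mean_adc: Optional[float] = None
    suvmax: Optional[float] = None
    k1: Optional[float] = None
    k2: Optional[float] = None
    k3: Optional[float] = None
    ki: Optional[float] = None
    mrfdg: Optional[float] = None
    mrfdg_peak_pe: Optional[float] = None
    mrfdg_peak_ser: Optional[float] = None
    mrfdg_k1: Optional[float] = None
    suvmax_peak_pe: Optional[float] = None
    suvmax_peak_ser: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise MpqError(f"unknown timepoint {self.timepoint!r}")

    @property
    def adc(self) -> Optional[float]:
        """Alias: the cohort-level metric name for ``mean_adc``."""
        return self.mean_adc

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def check_invariants(self) -> None:
        if (
            self.ftv is not None
            and self.washout_volume is not None
            and self.washout_volume > self.ftv + 1e-9
        ):
            raise MpqError("washout volume exceeds functional tumor volume")
        if self.ki is not None and self.k1 is not None and self.ki > self.k1 + 1e-12:
            raise MpqError("Ki exceeds K1, impossible for non-negative rates")


@dataclass
class TwoTissueParams:
    """Irreversible two-tissue compartment parameters (k4 = 0).

    ``ki`` is a derived quantity, K1*k3/(k2+k3), never stored; ``vb`` is
    the fractional blood volume contribution of whole-blood activity to
    the measured tissue curve.
    """

    k1: float  # mL/min/g
    k2: float  # 1/min
    k3: float  # 1/min
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise MpqError(f"{name} must be non-negative")
        if not (0 <= self.vb < 1):
            raise MpqError("vb must lie in [0, 1)")

    @property
    def ki(self) -> float:
        denom = self.k2 + self.k3
        if denom == 0.0:
            # k2 = k3 = 0: no trapping pathway, flux is zero.
            return 0.0
        return self.k1 * self.k3 / denom


@dataclass
class TwoTissueFit:
    """Fit result wrapping :class:`TwoTissueParams` with quality metadata."""

    params: TwoTissueParams
    success: bool
    weighted_rss: float
    n_frames: int
    n_starts: int
    message: str = ""
    degenerate: bool = False

    @property
    def ki(self) -> float:
        return self.params.ki
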