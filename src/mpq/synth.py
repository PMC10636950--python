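"""Synthetic phantoms and cohorts for the multimodal response pipeline.

Two decoupled layers:

* **Image layer** — digital tumor phantoms with prescribed enhancement
  kinetics (PE/SER), monoexponential diffusion decay, and two-tissue
  compartment tracer kinetics driven by a Feng-type arterial input
  function. Noiseless phantoms invert exactly under the quantification
  modules; noise models (Gaussian, Rician for DWI, duration-scaled
  Gaussian for PET) are explicit options.

* **Cohort layer** — per-patient percent-change tables whose group
  means/SDs are prescribed per metric and timepoint (defaults follow the
  published serial breast NAC cohort: e.g. mid-treatment peak PE
  -31.1 (12.6)% in responders vs -15.1 (28.0)% in non-responders), with
  recurrence times drawn from an exponential proportional-hazards model
  whose log-hazard is linear in (percent change)/5.

All randomness flows through a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ALL_METRICS,
    ImageVolume,
    DynamicPetSeries,
    MpqError,
    TimeActivityCurve,
    TwoTissueParams,
)
from .pet import two_tissue_frame_activity

# --------------------------------------------------------------------- phantoms


@dataclass
class RegionKinetics:
    """Ground-truth tissue properties for one phantom region."""

    pe: float = 0.8                       # (S1-S0)/S0
    ser: float = 1.3                      # (S1-S0)/(S2-S0)
    adc: float = 1.0e-3                   # mm^2/s
    pet: TwoTissueParams = field(
        default_factory=lambda: TwoTissueParams(0.10, 0.20, 0.05)
    )


@dataclass
class PhantomSpec:
    """Spherical-tumor digital phantom specification.

    The default grid (1 mm isotropic, radius 5 mm) yields a 515-voxel
    tumor — the number of unit-lattice points within a radius-5 sphere.
    """

    shape: tuple[int, int, int] = (20, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: Optional[tuple[float, float, float]] = None  # voxel indices
    radius_mm: float = 5.0
    tumor: RegionKinetics = field(default_factory=RegionKinetics)
    background: RegionKinetics = field(
        default_factory=lambda: RegionKinetics(
            pe=0.1, ser=0.8, adc=2.0e-3, pet=TwoTissueParams(0.02, 0.40, 0.002)
        )
    )
    s0_dce: float = 100.0
    s0_dwi: float = 1000.0
    noise_sd_rel: float = 0.0             # Gaussian sd relative to local signal
    dwi_noise: str = "gaussian"           # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0:
            raise MpqError("noise sd must be non-negative")
        if self.center is None:
            # Integer-voxel center: a radius-5 mm sphere on a 1 mm grid then
            # covers exactly 515 voxel centers (unit-lattice points in the ball).
            self.center = tuple(float(s // 2) for s in self.shape)
        extent_mm = [c * sp for c, sp in zip(self.center, self.spacing)] + [
            (s - 1 - c) * sp for s, c, sp in zip(self.shape, self.center, self.spacing)
        ]
        if self.radius_mm > min(extent_mm):
            raise MpqError("tumor sphere does not fit inside the grid")

    def tumor_mask(self) -> np.ndarray:
        grids = np.indices(self.shape).astype(float)
        dist2 = sum(
            ((g - c) * sp) ** 2
            for g, c, sp in zip(grids, self.center, self.spacing)
        )
        return dist2 <= self.radius_mm**2


def _fill(spec: PhantomSpec, tumor_value: float, bg_value: float) -> np.ndarray:
    mask = spec.tumor_mask()
    return np.where(mask, tumor_value, bg_value)


def make_dce_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, np.ndarray]:
    """DCE phase images (S0, S1, S2) plus the ground-truth tumor mask.

    Construction inverts the PE/SER definitions: S1 = S0*(1+PE) and
    S2 = S0 + (S1-S0)/SER, so noiseless phantoms reproduce the
    prescribed kinetics to float precision. A prescribed SER of 0 would
    require S2 = S0 exactly (undefined ratio) and is rejected.
    """
    for region in (spec.tumor, spec.background):
        if region.ser == 0:
            raise MpqError("prescribed SER of 0 is degenerate (requires S2 == S0)")
    mask = spec.tumor_mask()
    s0 = np.full(spec.shape, spec.s0_dce, dtype=float)
    pe = _fill(spec, spec.tumor.pe, spec.background.pe)
    ser = _fill(spec, spec.tumor.ser, spec.background.ser)
    s1 = s0 * (1.0 + pe)
    s2 = s0 + (s1 - s0) / ser
    if spec.noise_sd_rel > 0:
        rng = np.random.default_rng(spec.seed)
        s0, s1, s2 = (
            s + rng.normal(0.0, spec.noise_sd_rel * np.abs(s)) for s in (s0, s1, s2)
        )
    return (
        ImageVolume(s0, spec.spacing),
        ImageVolume(s1, spec.spacing),
        ImageVolume(s2, spec.spacing),
        mask,
    )


def make_dwi_phantom(
    spec: PhantomSpec, b_values: Sequence[float] = (0.0, 100.0, 800.0)
) -> list[ImageVolume]:
    """DWI volumes following S(b) = S(0) * exp(-b * ADC) per region."""
    if spec.tumor.adc < 0 or spec.background.adc < 0:
        raise MpqError("prescribed ADC must be non-negative")
    adc = _fill(spec, spec.tumor.adc, spec.background.adc)
    rng = np.random.default_rng(spec.seed + 1)
    volumes = []
    for b in b_values:
        signal = spec.s0_dwi * np.exp(-float(b) * adc)
        if spec.noise_sd_rel > 0:
            sd = spec.noise_sd_rel * spec.s0_dwi
            if spec.dwi_noise == "rician":
                signal = np.sqrt(
                    (signal + rng.normal(0.0, sd, spec.shape)) ** 2
                    + rng.normal(0.0, sd, spec.shape) ** 2
                )
            else:
                signal = signal + rng.normal(0.0, sd, spec.shape)
        volumes.append(ImageVolume(signal, spec.spacing))
    return volumes


# --------------------------------------------------------------- input function


@dataclass
class InputFunctionSpec:
    """Feng-type tri-exponential arterial input model.

    Cp(t) = (a1*t - a2 - a3)*exp(-l1*t) + a2*exp(-l2*t) + a3*exp(-l3*t)
    for t >= delay (0 before). The default coefficients are the classic
    FDG population shape scaled to a realistic peak of ~100 kBq/mL; they
    are configuration defaults for simulation, not measured values.
    """

    a1: float = 851.1225 * 0.1            # kBq/mL/min
    a2: float = 21.8798 * 0.1             # kBq/mL
    a3: float = 20.8113 * 0.1
    l1: float = 4.133859                  # 1/min
    l2: float = 0.01043449
    l3: float = 0.1190996
    delay_min: float = 0.0


def evaluate_input_function(spec: InputFunctionSpec, t: np.ndarray) -> np.ndarray:
    tt = np.asarray(t, dtype=float) - spec.delay_min
    cp = np.where(
        tt >= 0,
        (spec.a1 * tt - spec.a2 - spec.a3) * np.exp(-spec.l1 * tt)
        + spec.a2 * np.exp(-spec.l2 * tt)
        + spec.a3 * np.exp(-spec.l3 * tt),
        0.0,
    )
    return cp


def simulate_input_function(
    spec: InputFunctionSpec, times_min: np.ndarray
) -> TimeActivityCurve:
    """Evaluate the arterial input model on the requested time grid."""
    times = np.atleast_1d(np.asarray(times_min, dtype=float))
    if times.size == 0:
        raise MpqError("empty time grid")
    cp = evaluate_input_function(spec, times)
    if np.any(cp < -1e-9):
        raise MpqError("input-function coefficients produce negative activity")
    return TimeActivityCurve(times, np.clip(cp, 0.0, None), label="blood")


def simulate_tumor_tac(
    params: TwoTissueParams,
    cp: TimeActivityCurve,
    frame_start: np.ndarray,
    frame_end: np.ndarray,
    dt: float = 0.05,
) -> TimeActivityCurve:
    """Frame-averaged tissue curve from the irreversible 2TC forward model."""
    frame_start = np.asarray(frame_start, dtype=float)
    frame_end = np.asarray(frame_end, dtype=float)
    if frame_start.size and frame_end[-1] > cp.midtimes[-1] + 1e-9:
        raise MpqError("frames extend beyond the input-function support")
    activity = two_tissue_frame_activity(params, cp, frame_start, frame_end, dt=dt)
    return TimeActivityCurve(0.5 * (frame_start + frame_end), activity, label="tumor")


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """A 60-minute dynamic schedule: fine early frames, coarse late frames."""
    durations = [10 / 60] * 12 + [0.5] * 4 + [1.0] * 4 + [3.0] * 4 + [5.0] * 8
    edges = np.concatenate(([0.0], np.cumsum(durations)))
    return edges[:-1], edges[1:]


def make_pet_phantom(
    spec: PhantomSpec,
    input_spec: Optional[InputFunctionSpec] = None,
    frame_start: Optional[np.ndarray] = None,
    frame_end: Optional[np.ndarray] = None,
    dt: float = 0.05,
) -> tuple[DynamicPetSeries, TimeActivityCurve, np.ndarray]:
    """Dynamic PET frame series with 2TC kinetics per region.

    Returns (series, blood input function, truth mask). PET noise, when
    enabled, is Gaussian with variance proportional to activity divided
    by frame duration — the standard reconstruction-domain
    approximation of count statistics.
    """
    if input_spec is None:
        input_spec = InputFunctionSpec()
    if frame_start is None or frame_end is None:
        frame_start, frame_end = default_frame_schedule()
    fine_t = np.arange(0.0, float(frame_end[-1]) + dt, dt)
    cp = simulate_input_function(input_spec, fine_t)
    tumor_tac = two_tissue_frame_activity(spec.tumor.pet, cp, frame_start, frame_end, dt=dt)
    bg_tac = two_tissue_frame_activity(spec.background.pet, cp, frame_start, frame_end, dt=dt)
    mask = spec.tumor_mask()
    rng = np.random.default_rng(spec.seed + 2)
    frames = []
    durations = frame_end - frame_start
    for i in range(len(frame_start)):
        vox = np.where(mask, tumor_tac[i], bg_tac[i]).astype(float)
        if spec.noise_sd_rel > 0:
            sd = spec.noise_sd_rel * np.sqrt(
                np.maximum(vox, 1e-6) / max(durations[i], 1e-6)
            )
            vox = vox + rng.normal(0.0, sd)
        frames.append(ImageVolume(vox, spec.spacing))
    series = DynamicPetSeries(frames, frame_start, frame_end)
    return series, cp, mask


# ----------------------------------------------------------------------- cohort

# Group percent-change distributions (mean, SD) per metric and timepoint,
# responders (RCB 0/I) vs non-responders (RCB II/III), as published for
# the 35-patient serial imaging cohort.
TABLE_EFFECTS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    #                mid: (resp_mean, resp_sd, nonresp_mean, nonresp_sd)
    "k1":                 {"mid": (-79.9, 14.6, -59.1, 46.2), "post": (-92.0, 12.6, -75.1, 26.7)},
    "mrfdg":              {"mid": (-86.5, 19.1, -80.5, 40.7), "post": (-94.1, 13.2, -85.8, 23.3)},
    "suvmax":             {"mid": (-72.8, 21.2, -59.0, 35.4), "post": (-76.3, 8.5, -64.1, 28.1)},
    "adc":                {"mid": (22.2, 20.4, 27.6, 40.0),   "post": (47.5, 34.1, 30.0, 52.9)},
    "peak_pe":            {"mid": (-31.1, 12.6, -15.1, 28.0), "post": (-65.6, 19.0, -31.4, 55.9)},
    "peak_ser":           {"mid": (-25.4, 21.9, -16.9, 27.1), "post": (-53.6, 8.6, -33.6, 24.5)},
    "ftv":                {"mid": (-81.6, 16.4, -61.8, 32.8), "post": (-92.3, 7.8, -86.5, 27.9)},
    "washout_volume":     {"mid": (-88.4, 8.5, -76.5, 21.4),  "post": (-95.3, 5.0, -93.9, 17.3)},
    "longest_dimension":  {"mid": (-34.6, 62.4, -25.9, 52.2), "post": (-100.0, 46.6, -39.4, 75.6)},
    "mrfdg_peak_pe":      {"mid": (-80.1, 27.6, -72.8, 42.6), "post": (-88.1, 41.7, -79.6, 54.0)},
    "mrfdg_peak_ser":     {"mid": (-81.2, 25.5, -75.1, 40.7), "post": (-86.7, 27.2, -80.7, 45.4)},
    "mrfdg_k1":           {"mid": (-34.2, 87.2, -56.0, 77.1), "post": (-49.3, 95.0, -33.0, 83.3)},
    "suvmax_peak_pe":     {"mid": (-57.7, 25.0, -44.0, 39.7), "post": (-32.6, 72.0, -33.6, 50.9)},
    "suvmax_peak_ser":    {"mid": (-61.9, 26.1, -48.3, 40.7), "post": (-49.4, 31.8, -37.1, 43.0)},
}

# Hazard linkage defaults: log HR per 5%-change unit at mid-treatment for
# the metrics whose serial changes were predictive of recurrence.
DEFAULT_HAZARD_COEFS: dict[str, float] = {
    "k1": math.log(1.03),
    "mrfdg": math.log(1.04),
    "washout_volume": math.log(1.19),
    "peak_ser": math.log(1.38),
}

# Typical baseline magnitudes for drawing lognormal baseline values
# (plausible breast-tumor scales; used only to give the baseline
# correlation analyses realistic inputs).
BASELINE_SCALES: dict[str, float] = {
    "k1": 0.15, "mrfdg": 0.5, "suvmax": 6.0, "adc": 1.1,
    "peak_pe": 1.3, "peak_ser": 1.1, "ftv": 25.0,
    "washout_volume": 8.0, "longest_dimension": 45.0,
}


@dataclass
class CohortEffectSpec:
    """Statistical specification of a synthetic serial-imaging cohort."""

    n_responders: int = 11
    n_nonresponders: int = 24
    effects: dict = field(default_factory=lambda: {
        m: {tp: v for tp, v in tps.items()} for m, tps in TABLE_EFFECTS.items()
    })
    hazard_coefs: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_COEFS))
    hazard_timepoint: str = "mid"
    base_hazard_per_year: float = 0.03
    censor_low_years: float = 1.1
    censor_high_years: float = 9.8
    draw_baselines: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise MpqError("group sizes must be at least 1")
        for metric, tps in self.effects.items():
            for tp, (m_r, s_r, m_n, s_n) in tps.items():
                if s_r < 0 or s_n < 0:
                    raise MpqError(f"negative SD for {metric}/{tp}")
        if not all(np.isfinite(list(self.hazard_coefs.values()) or [0.0])):
            raise MpqError("hazard coefficients must be finite")


def make_cohort(spec: CohortEffectSpec) -> pd.DataFrame:
    """Draw a per-patient cohort table with planted effects.

    Responder status is drawn first (fixed group sizes); percent changes
    are Normal(group mean, group SD) per metric/timepoint; RFS follows
    an exponential proportional-hazards model whose log-hazard is linear
    in (percent change)/5, centered at the population mean so the
    marginal event rate stays near the base hazard; censoring is uniform
    over the follow-up range. Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_responders + spec.n_nonresponders
    responder = np.concatenate(
        [np.ones(spec.n_responders, bool), np.zeros(spec.n_nonresponders, bool)]
    )
    # RCB labels consistent with the responder flag (0 vs I, II vs III).
    rcb = np.where(
        responder,
        np.where(rng.random(n) < 0.7, "0", "I"),
        np.where(rng.random(n) < 0.7, "II", "III"),
    )
    df = pd.DataFrame({
        "patient_id": [f"SYN{idx:04d}" for idx in range(n)],
        "rcb_class": rcb,
        "responder": responder,
    })

    for metric, tps in spec.effects.items():
        for tp, (m_r, s_r, m_n, s_n) in tps.items():
            mean = np.where(responder, m_r, m_n)
            sd = np.where(responder, s_r, s_n)
            df[f"pct_{metric}_{tp}"] = rng.normal(mean, sd)

    if spec.draw_baselines:
        for metric, scale in BASELINE_SCALES.items():
            df[f"{metric}_baseline"] = scale * rng.lognormal(0.0, 0.4, n)

    # Proportional-hazards recurrence times on centered covariates.
    log_hr = np.zeros(n)
    for metric, beta_per_5 in spec.hazard_coefs.items():
        col = f"pct_{metric}_{spec.hazard_timepoint}"
        if col not in df.columns:
            raise MpqError(f"hazard linkage refers to missing column {col}")
        x = df[col].to_numpy() / 5.0
        log_hr += beta_per_5 * (x - x.mean())
    rate = spec.base_hazard_per_year * np.exp(log_hr)
    if not np.all(np.isfinite(rate)):
        raise MpqError("hazard coefficients produce non-finite rates")
    event_time = rng.exponential(1.0 / np.maximum(rate, 1e-12))
    censor_time = rng.uniform(spec.censor_low_years, spec.censor_high_years, n)
    df["rfs_time_years"] = np.minimum(event_time, censor_time)
    df["rfs_event"] = event_time <= censor_time
    return df


# ------------------------------------------------------------- study fixture


def make_synthetic_study(
    out_dir, seed: int = 0, n_patients: int = 6, noise_sd_rel: float = 0.02
):
    """Write a small image-level study (phantoms + YAML manifest) to disk.

    Each patient gets DCE/DWI/PET phantoms at baseline, mid, and post,
    with tumor kinetics that respond to therapy (responders shrink and
    lose enhancement, delivery, and trapping faster than
    non-responders); one patient is MRI-only to exercise per-metric
    missingness. Returns the manifest path.
    """
    import yaml as _yaml
    from pathlib import Path as _Path

    from .io import write_tac, write_volume

    out_dir = _Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    shape, spacing = (20, 40, 40), (1.5, 1.0, 1.0)
    frame_start, frame_end = default_frame_schedule()

    # (PE, SER, ADC mm^2/s, K1, k2, k3, radius mm) multiplicative course.
    course = {
        True: {  # responder
            "baseline": (0.90, 1.40, 0.90e-3, 0.12, 0.25, 0.060, 8.0),
            "mid":      (0.62, 1.15, 1.10e-3, 0.06, 0.25, 0.030, 7.2),
            "post":     (0.55, 1.00, 1.30e-3, 0.02, 0.25, 0.008, 6.6),
        },
        False: {  # non-responder
            "baseline": (0.90, 1.40, 0.90e-3, 0.12, 0.25, 0.060, 8.0),
            "mid":      (0.78, 1.30, 1.00e-3, 0.09, 0.25, 0.048, 7.8),
            "post":     (0.65, 1.20, 1.10e-3, 0.06, 0.25, 0.036, 7.6),
        },
    }

    patients = []
    for i in range(n_patients):
        responder = i < max(1, n_patients // 3)
        pid = f"P{i:02d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        mri_only = i == n_patients - 1
        tp_entries = {}
        for tp in ("baseline", "mid", "post"):
            pe, ser, adc, k1, k2, k3, radius = course[responder][tp]
            jitter = 1.0 + 0.05 * rng.standard_normal()
            spec = PhantomSpec(
                shape=shape,
                spacing=spacing,
                radius_mm=radius,
                tumor=RegionKinetics(
                    pe=pe * jitter, ser=ser, adc=adc,
                    pet=TwoTissueParams(k1 * jitter, k2, k3 * jitter),
                ),
                noise_sd_rel=noise_sd_rel,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            tdir = pdir / tp
            tdir.mkdir(exist_ok=True)
            s0, s1, s2, _ = make_dce_phantom(spec)
            for name, vol in (("s0", s0), ("s1", s1), ("s2", s2)):
                write_volume(vol, tdir / f"{name}.nii")
            for b, vol in zip((0, 100, 800), make_dwi_phantom(spec)):
                write_volume(vol, tdir / f"b{b}.nii")
            entry = {
                "dce": {f"{n}": f"{pid}/{tp}/{n}.nii" for n in ("s0", "s1", "s2")},
                "dwi": {
                    "volumes": [f"{pid}/{tp}/b{b}.nii" for b in (0, 100, 800)],
                    "b_values": [0, 100, 800],
                },
            }
            if not mri_only:
                series, cp, _ = make_pet_phantom(
                    spec, frame_start=frame_start, frame_end=frame_end
                )
                frame_files = []
                for j, frame in enumerate(series.frames):
                    fname = f"{pid}/{tp}/frame{j:03d}.nii"
                    write_volume(frame, out_dir / fname)
                    frame_files.append(fname)
                pd.DataFrame(
                    {"start_min": frame_start, "end_min": frame_end}
                ).to_csv(tdir / "timing.csv", index=False)
                write_tac(cp, tdir / "blood_tac.csv")
                entry["pet"] = {
                    "frames": frame_files,
                    "timing": f"{pid}/{tp}/timing.csv",
                    "blood_tac": f"{pid}/{tp}/blood_tac.csv",
                }
            tp_entries[tp] = entry

        # Outcomes: responders recur rarely, non-responders more often.
        recurs = bool(rng.random() < (0.15 if responder else 0.5))
        rfs = float(rng.uniform(0.8, 4.0)) if recurs else float(rng.uniform(5.0, 9.5))
        patients.append({
            "id": pid,
            "physiology": {
                "injected_dose_mbq": float(np.round(rng.uniform(260, 400), 1)),
                "body_weight_kg": float(np.round(rng.uniform(55, 90), 1)),
                "plasma_glucose": float(np.round(rng.uniform(4.0, 6.5), 2)),
                "glucose_unit": "mmol/L",
            },
            "outcome": {
                "rcb_class": ("0" if responder else "II"),
                "rfs_time_years": round(rfs, 3),
                "rfs_event": int(recurs),
            },
            "timepoints": tp_entries,
        })

    manifest = {"seeds": {"study": seed}, "patients": patients}
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(_yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
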