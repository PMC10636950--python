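"""Static SUV quantification and dynamic FDG two-tissue compartment modeling.

The kinetic model is the irreversible two-tissue compartment model
(k4 = 0) conventionally used for FDG over a 60-minute acquisition:

    dC1/dt = K1*Cp - (k2 + k3)*C1
    dC2/dt = k3*C1

whose measured tissue concentration (free + trapped, plus an optional
fractional blood signal) has the closed-form impulse response

    C_T(t) = K1 * (k3 + k2*exp(-(k2+k3)*t)) / (k2+k3)  convolved with  Cp(t)
    C_meas(t) = (1 - Vb)*C_T(t) + Vb*Cp(t)

K1 (mL/min/g) is glucose delivery, k2 (1/min) efflux back to blood, k3
(1/min) hexokinase-mediated trapping. The net trapping flux is
Ki = K1*k3/(k2+k3), and the metabolic rate of FDG is
MRFDG = Ki * [plasma glucose] (no lumped-constant correction).

The convolution is evaluated on a uniform fine time grid with linear
interpolation of the input function, then averaged over each frame
interval — the same forward model serves simulation and fitting.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    DynamicPetSeries,
    ImageVolume,
    MpqError,
    PatientPhysiology,
    TimeActivityCurve,
    TwoTissueFit,
    TwoTissueParams,
)

log = logging.getLogger("mpq.pet")


# ---------------------------------------------------------------- forward model

def two_tissue_frame_activity(
    params: TwoTissueParams,
    cp: TimeActivityCurve,
    frame_start: np.ndarray,
    frame_end: np.ndarray,
    dt: float = 0.05,
) -> np.ndarray:
    """Frame-averaged tissue activity from the irreversible 2TC model.

    ``cp`` is linearly interpolated onto a uniform grid of step ``dt``
    (minutes) from time 0 to the last frame end; the impulse response is
    convolved against it, the optional blood fraction added, and the
    result averaged over each [start, end) frame interval.
    """
    frame_start = np.asarray(frame_start, dtype=float)
    frame_end = np.asarray(frame_end, dtype=float)
    if np.any(frame_end <= frame_start):
        raise MpqError("frame_end must exceed frame_start")
    t_max = float(frame_end.max())
    n = int(np.ceil(t_max / dt)) + 1
    t = np.arange(n + 1) * dt
    cp_grid = np.interp(t, cp.midtimes, cp.activity, left=0.0, right=float(cp.activity[-1]))

    k1, k2, k3, vb = params.k1, params.k2, params.k3, params.vb
    ksum = k2 + k3
    if ksum > 0:
        h = k1 * (k3 + k2 * np.exp(-ksum * t)) / ksum
    else:
        h = np.full_like(t, k1)  # pure accumulation: C_T = K1 * integral of Cp
    # Trapezoid-rule convolution: rectangle-rule conv minus half the
    # endpoint terms, second-order accurate in dt for smooth inputs.
    full = np.convolve(h, cp_grid)[: t.size]
    ct = dt * (full - 0.5 * (h[0] * cp_grid + h * cp_grid[0]))
    meas = (1.0 - vb) * ct + vb * cp_grid

    # Average over each frame by integrating the cumulative trapezoid.
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (meas[1:] + meas[:-1]) * dt)))

    def integral(up_to: np.ndarray) -> np.ndarray:
        idx = np.clip(up_to / dt, 0, t.size - 1)
        lo = np.floor(idx).astype(int)
        frac = idx - lo
        hi = np.minimum(lo + 1, t.size - 1)
        return cum[lo] + frac * (cum[hi] - cum[lo])

    return (integral(frame_end) - integral(frame_start)) / (frame_end - frame_start)


# -------------------------------------------------------------------- static SUV

def summed_suv_image(
    series: DynamicPetSeries,
    phys: PatientPhysiology,
    window: tuple[float, float] = (30.0, 60.0),
) -> ImageVolume:
    """Duration-weighted mean activity over the window, normalized to SUV.

    SUV = C [kBq/mL] * body weight [kg] / injected dose [MBq], the usual
    body-weight normalization with tissue density taken as 1 g/mL
    (kBq/mL * kg / MBq = dimensionless g/mL-normalized uptake).
    """
    lo, hi = float(window[0]), float(window[1])
    inside = (series.frame_start >= lo - 1e-9) & (series.frame_end <= hi + 1e-9)
    if not inside.any():
        raise MpqError(f"no frames inside SUV window [{lo}, {hi}] min")
    covered = series.frame_end[inside].max() - series.frame_start[inside].min()
    if covered < 0.5 * (hi - lo):
        raise MpqError("frames cover less than half the requested SUV window")
    durations = series.durations[inside]
    stack = np.stack([f.voxels for f, use in zip(series.frames, inside) if use])
    mean_activity = np.tensordot(durations, stack, axes=(0, 0)) / durations.sum()
    # C * weight / dose with dose in kBq and weight in g: the 1000s from
    # MBq->kBq and kg->g cancel, and mL == g at density 1 g/mL.
    suv = mean_activity * phys.body_weight_kg / phys.injected_dose_mbq
    return ImageVolume(suv, series.frames[0].spacing)


def sphere_voi_mask(
    volume: ImageVolume,
    center: tuple[float, float, float],
    volume_cc: float = 1.0,
) -> np.ndarray:
    """Boolean mask of a sphere of the requested volume at a voxel-index center."""
    radius_mm = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    grids = np.indices(volume.shape).astype(float)
    dist2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, center, volume.spacing)
    )
    mask = dist2 <= radius_mm**2
    if not mask.any():
        raise MpqError("VOI sphere contains no voxel centers")
    return mask


def suvmax_in_voi(
    suv_image: ImageVolume,
    voi_center: tuple[float, float, float],
    voi_volume_cc: float = 1.0,
) -> float:
    """Maximum SUV within a ~1 cc sphere centered on the lesion hotspot."""
    center = np.asarray(voi_center, dtype=float)
    if np.any(center < 0) or np.any(center > np.asarray(suv_image.shape) - 1):
        raise MpqError(f"VOI center {voi_center} outside image of shape {suv_image.shape}")
    mask = sphere_voi_mask(suv_image, tuple(center), voi_volume_cc)
    return float(np.nanmax(suv_image.voxels[mask]))


def locate_lesion_center(
    suv_image: ImageVolume, threshold_frac: float = 0.5
) -> tuple[float, float, float]:
    """Lesion localization surrogate: centroid of the hot region.

    Takes the connected component (26-connectivity) of voxels above
    ``threshold_frac`` of the maximum that contains the hottest voxel,
    and returns its center of mass in voxel indices. This stands in for
    the manual placement of a VOI encompassing the pixels with the most
    uptake.
    """
    from scipy import ndimage

    v = np.nan_to_num(suv_image.voxels, nan=-np.inf)
    peak = np.unravel_index(int(np.argmax(v)), v.shape)
    above = v >= threshold_frac * v[peak]
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels == labels[peak]
    return tuple(float(c) for c in ndimage.center_of_mass(comp))


def extract_tac(series: DynamicPetSeries, voi: np.ndarray, label: str = "tumor") -> TimeActivityCurve:
    """Per-frame VOI-mean activity at frame midtimes."""
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != series.frames[0].shape:
        raise MpqError("VOI grid does not match the dynamic series")
    if not voi.any():
        raise MpqError("empty VOI")
    activity = np.array([float(f.voxels[voi].mean()) for f in series.frames])
    return TimeActivityCurve(series.midtimes, activity, label=label)


# ----------------------------------------------------------------------- fitting

# Deterministic multistart lattice: plausible breast-FDG values spanning
# low/high delivery, efflux, and trapping. No RNG enters the fit.
_START_LATTICE: tuple[tuple[float, float, float], ...] = (
    (0.05, 0.10, 0.01),
    (0.05, 0.50, 0.10),
    (0.10, 0.20, 0.05),
    (0.10, 0.60, 0.02),
    (0.20, 0.30, 0.10),
    (0.20, 1.00, 0.30),
    (0.40, 0.80, 0.05),
    (0.60, 1.50, 0.20),
)


def fit_two_tissue(
    tac: TimeActivityCurve,
    cp: TimeActivityCurve,
    frame_start: Optional[np.ndarray] = None,
    frame_end: Optional[np.ndarray] = None,
    fit_vb: bool = False,
    k_upper: float = 5.0,
    dt: float = 0.05,
    weight_floor: float = 1e-3,
) -> TwoTissueFit:
    """Weighted nonlinear least-squares fit of the irreversible 2TC model.

    Weights approximate count statistics as frame_duration /
    max(activity, floor); optimization is bounded trust-region least
    squares started from a fixed lattice of 8 plausible parameter sets
    (plus Vb = 0.05 when ``fit_vb``); the best weighted residual wins,
    ties broken by lattice order. The procedure is fully deterministic.

    Frame intervals default to intervals centered on the TAC midtimes.
    """
    if tac.midtimes.size < 4:
        raise MpqError("fit requires at least 4 frames")
    if cp.midtimes[-1] < tac.midtimes[-1] - 1e-6:
        raise MpqError("input function does not cover the tissue curve support")
    if frame_start is None or frame_end is None:
        edges = np.concatenate(
            ([0.0], 0.5 * (tac.midtimes[1:] + tac.midtimes[:-1]), [tac.midtimes[-1]])
        )
        edges[-1] = tac.midtimes[-1] + (tac.midtimes[-1] - edges[-2])
        frame_start, frame_end = edges[:-1], edges[1:]
    frame_start = np.asarray(frame_start, dtype=float)
    frame_end = np.asarray(frame_end, dtype=float)

    y = tac.activity
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        # Identically zero tissue curve: no delivery.
        params = TwoTissueParams(0.0, 0.0, 0.0)
        return TwoTissueFit(params, True, 0.0, y.size, 0, "zero tissue curve", degenerate=True)
    if np.min(y) < -0.25 * scale:
        raise MpqError("tissue activities are negative beyond noise tolerance")

    durations = frame_end - frame_start
    w = np.sqrt(durations / np.maximum(np.abs(y), weight_floor * scale))
    w /= w.max()

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = TwoTissueParams(theta[0], theta[1], theta[2], theta[3] if fit_vb else 0.0)
        model = two_tissue_frame_activity(p, cp, frame_start, frame_end, dt=dt)
        return w * (model - y)

    nll = 4 if fit_vb else 3
    lower = np.zeros(nll)
    upper = np.array([k_upper] * 3 + ([0.5] if fit_vb else []))
    best = None
    n_ok = 0
    for start in _START_LATTICE:
        theta0 = np.array(list(start) + ([0.05] if fit_vb else []))
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.debug("fit start %s failed: %s", start, exc)
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        params = TwoTissueParams(0.0, 0.0, 0.0)
        return TwoTissueFit(
            params, False, np.inf, y.size, 0, "all starts failed to converge"
        )
    theta = best.x
    params = TwoTissueParams(
        float(theta[0]), float(theta[1]), float(theta[2]),
        float(theta[3]) if fit_vb else 0.0,
    )
    return TwoTissueFit(
        params=params,
        success=True,
        weighted_rss=float(2.0 * best.cost),
        n_frames=int(y.size),
        n_starts=n_ok,
        message="converged",
    )


def metabolic_rate_fdg(
    params: TwoTissueParams,
    phys: PatientPhysiology,
    expected_glucose_unit: Optional[str] = None,
) -> float:
    """MRFDG = Ki * [plasma glucose], no lumped-constant correction.

    Units are (mL/min/g) times the declared glucose concentration unit;
    if the caller declares an expected unit it must match the
    physiology record — concentrations are never converted silently.
    """
    if phys.plasma_glucose is None:
        raise MpqError("plasma glucose required for MRFDG")
    if expected_glucose_unit is not None and expected_glucose_unit != phys.glucose_unit:
        raise MpqError(
            f"glucose unit mismatch: physiology declares {phys.glucose_unit!r}, "
            f"analysis expects {expected_glucose_unit!r}"
        )
    return params.ki * phys.plasma_glucose
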