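"""Monoexponential ADC fitting for diffusion-weighted MRI.

The signal model is S(b) = S(0) * exp(-b * ADC); the default fit is
ordinary least squares on ln S(b) (log-linear), which is deterministic
and reduces to the closed-form two-point solution when exactly two
b-values are supplied. A nonlinear least-squares option is available
for completeness. ADC carries units mm^2/s with b in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import ImageVolume, MpqError, require_same_grid
from .dce import TumorMask


@dataclass
class AdcFitResult:
    """Per-voxel ADC map with an explicit validity flag.

    Voxels with any non-positive signal across b-values cannot enter the
    log-domain fit; they are flagged invalid (NaN in the maps), never
    silently zeroed.
    """

    adc_map: ImageVolume      # mm^2/s
    s0_map: ImageVolume       # fitted b=0 signal
    valid: np.ndarray         # boolean


def fit_adc(
    volumes: list[ImageVolume],
    b_values: list[float],
    method: str = "loglinear",
) -> AdcFitResult:
    """Voxel-wise monoexponential fit over the supplied b-values.

    ln S(b) = ln S(0) - b * ADC, solved by OLS per voxel (vectorized).
    The fitted ADC is reported as-is — under noise it can dip slightly
    negative; the validity flag marks only voxels whose signals are not
    all positive (unusable in the log domain). Physical clipping, if
    wanted, is the caller's decision.
    """
    if len(volumes) != len(b_values):
        raise MpqError("need one volume per b-value")
    b = np.asarray(b_values, dtype=float)
    if b.size < 2 or np.unique(b).size < 2:
        raise MpqError("ADC fit requires at least two distinct b-values")
    require_same_grid(*volumes)
    spacing = volumes[0].spacing
    signals = np.stack([v.voxels for v in volumes], axis=0)  # (nb, z, y, x)
    valid = np.all(signals > 0, axis=0)

    if method == "loglinear":
        logs = np.where(signals > 0, np.log(np.where(signals > 0, signals, 1.0)), 0.0)
        # OLS slope/intercept against b, closed form.
        bm = b.mean()
        bc = b - bm
        denom = float((bc**2).sum())
        slope = np.tensordot(bc, logs, axes=(0, 0)) / denom
        intercept = logs.mean(axis=0) - slope * bm
        adc = -slope
        s0 = np.exp(intercept)
    elif method == "nonlinear":
        adc = np.full(signals.shape[1:], np.nan)
        s0 = np.full(signals.shape[1:], np.nan)
        model = lambda bb, s0_, d: s0_ * np.exp(-bb * d)  # noqa: E731
        for index in np.argwhere(valid):
            y = signals[(slice(None), *index)]
            try:
                popt, _ = curve_fit(model, b, y, p0=(y[0], 1e-3), maxfev=2000)
                s0[tuple(index)], adc[tuple(index)] = popt
            except RuntimeError:
                valid[tuple(index)] = False
    else:
        raise MpqError(f"unknown ADC fit method {method!r}")

    adc = np.where(valid, adc, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return AdcFitResult(
        adc_map=ImageVolume(adc, spacing),
        s0_map=ImageVolume(s0, spacing),
        valid=valid,
    )


def roi_mean_adc(result: AdcFitResult, roi: TumorMask) -> tuple[float, int]:
    """Mean ADC over valid ROI voxels; also reports how many were excluded.

    Raises if the ROI is empty or contains no valid fit voxels.
    """
    if roi.empty:
        raise MpqError("roi_mean_adc: empty ROI")
    if roi.mask.shape != result.adc_map.shape:
        raise MpqError("roi_mean_adc: ROI grid does not match ADC map")
    in_roi = roi.mask
    usable = in_roi & result.valid & np.isfinite(result.adc_map.voxels)
    n_excluded = int(in_roi.sum() - usable.sum())
    if not usable.any():
        raise MpqError("roi_mean_adc: no valid voxels in ROI")
    return float(result.adc_map.voxels[usable].mean()), n_excluded
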