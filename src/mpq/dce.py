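"""Voxel-wise DCE-MRI enhancement kinetics and tumor morphology.

Two maps drive the analysis:

* percent enhancement  PE  = (S1 - S0) / S0
* signal enhancement ratio SER = (S1 - S0) / (S2 - S0)

with S0 the pre-contrast, S1 the early (2 min) and S2 the delayed
(8 min) post-contrast T1-weighted signals. SER > 1 marks washout
kinetics between the early and delayed phases.

Derived lesion measures: 3D segmentation at PE >= 0.50, hotspot peak PE
and peak SER (highest mean over an in-plane 3x3 tumor subregion),
functional tumor volume (volume with PE >= 0.50, cc), washout volume
(volume with SER >= 1.1 within the tumor, cc), and longest dimension
(maximum pairwise distance between tumor voxel centers, mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import ImageVolume, MpqError, require_same_grid

log = logging.getLogger("mpq.dce")


@dataclass
class TumorMask:
    """Boolean tumor mask with connected-component bookkeeping."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    labels: Optional[np.ndarray] = None
    n_components: int = 0
    selected_label: Optional[int] = None

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


def compute_pe_map(s0: ImageVolume, s1: ImageVolume) -> ImageVolume:
    """Percent-enhancement map (S1 - S0)/S0; S0 <= 0 voxels are NaN-masked."""
    require_same_grid(s0, s1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = (s1.voxels - s0.voxels) / s0.voxels
    pe = np.where(s0.voxels > 0, pe, np.nan)
    return ImageVolume(pe, s0.spacing)


def compute_ser_map(
    s0: ImageVolume, s1: ImageVolume, s2: ImageVolume, epsilon: float = 1e-6
) -> ImageVolume:
    """Signal-enhancement-ratio map (S1 - S0)/(S2 - S0).

    Voxels where |S2 - S0| <= epsilon * max(S0, 1) have an undefined
    ratio and are NaN-masked rather than returned as huge numbers.
    """
    require_same_grid(s0, s1, s2)
    denom = s2.voxels - s0.voxels
    guard = epsilon * np.maximum(s0.voxels, 1.0)
    valid = np.abs(denom) > guard
    with np.errstate(divide="ignore", invalid="ignore"):
        ser = (s1.voxels - s0.voxels) / denom
    ser = np.where(valid, ser, np.nan)
    return ImageVolume(ser, s0.spacing)


def segment_tumor(
    pe_map: ImageVolume,
    threshold: float = 0.50,
    seed_point: Optional[tuple[int, int, int]] = None,
) -> TumorMask:
    """3D tumor segmentation: PE >= threshold, 26-connected components.

    With a ``seed_point`` (slice, row, col) the component containing it
    is kept, the deterministic surrogate for manual lesion
    identification; otherwise the largest component is kept. An empty
    threshold set returns an empty mask ("no enhancing lesion"), not an
    exception.
    """
    above = np.nan_to_num(pe_map.voxels, nan=-np.inf) >= threshold
    if not above.any():
        log.info("segment_tumor: no enhancing lesion at threshold %.2f", threshold)
        return TumorMask(above, pe_map.spacing, n_components=0)
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    if seed_point is not None:
        seed_label = int(labels[tuple(seed_point)])
        if seed_label == 0:
            raise MpqError(f"seed point {seed_point} is not inside an enhancing region")
        chosen = seed_label
    else:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        chosen = int(np.argmax(sizes)) + 1
    return TumorMask(
        mask=labels == chosen,
        spacing=pe_map.spacing,
        labels=labels,
        n_components=int(n),
        selected_label=chosen,
    )


def hotspot_peak(map_volume: ImageVolume, mask: TumorMask, window: int = 3) -> float:
    """Peak value: highest mean of an in-plane ``window x window`` tumor subregion.

    Windows must lie fully inside the mask (and contain only valid,
    non-NaN map voxels); windows straddling the tumor boundary are
    excluded. If no window fits — a tiny lesion — the maximum single
    valid voxel is returned with a logged warning.
    """
    if mask.empty:
        raise MpqError("hotspot_peak: empty mask")
    if window % 2 != 1 or window < 1:
        raise MpqError("hotspot window must be a positive odd integer")
    values = map_volume.voxels
    eligible = mask.mask & np.isfinite(values)
    if not eligible.any():
        raise MpqError("hotspot_peak: no valid map voxels inside mask")
    footprint = np.zeros((1, window, window), dtype=bool)
    footprint[0] = True
    # A window fits iff every in-plane neighbor is eligible: erosion test.
    fits = ndimage.minimum_filter(
        eligible.astype(np.uint8), footprint=footprint, mode="constant", cval=0
    ).astype(bool)
    if not fits.any():
        log.warning(
            "hotspot_peak: no %dx%d window fits inside the mask; "
            "falling back to the single-voxel maximum",
            window,
            window,
        )
        return float(np.nanmax(np.where(eligible, values, np.nan)))
    means = ndimage.uniform_filter(
        np.where(eligible, values, 0.0), size=(1, window, window), mode="constant"
    )
    return float(means[fits].max())


def functional_tumor_volume(
    pe_map: ImageVolume, mask: TumorMask, threshold: float = 0.50
) -> float:
    """Total volume (cc) of in-mask voxels with PE >= threshold."""
    qualifying = mask.mask & (np.nan_to_num(pe_map.voxels, nan=-np.inf) >= threshold)
    return float(qualifying.sum()) * float(np.prod(mask.spacing)) / 1000.0


def washout_volume(
    ser_map: ImageVolume, mask: TumorMask, threshold: float = 1.1
) -> float:
    """Total volume (cc) of in-mask voxels with SER >= threshold.

    Evaluated within the segmented tumor so that washout volume can
    never exceed the functional tumor volume.
    """
    qualifying = mask.mask & (np.nan_to_num(ser_map.voxels, nan=-np.inf) >= threshold)
    return float(qualifying.sum()) * float(np.prod(mask.spacing)) / 1000.0


def longest_dimension(mask: TumorMask) -> float:
    """Maximum pairwise physical distance (mm) between mask voxel centers.

    For large masks the search is restricted to convex-hull vertices,
    which contain the diametral pair; small masks are brute-forced.
    """
    if mask.empty:
        raise MpqError("longest_dimension: empty mask")
    idx = np.argwhere(mask.mask).astype(float)
    pts = idx * np.asarray(mask.spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) masks: brute force
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())
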