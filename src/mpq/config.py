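"""Analysis configuration with clinical-protocol default thresholds.

All tunable thresholds of the pipeline live here so that a single YAML
file documents an analysis run. Defaults follow the standard breast
DCE/SER protocol: PE segmentation threshold 0.50, SER washout threshold
1.1, in-plane 3x3 hotspot window, SUV summation window 30-60 min post
injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import MpqError


@dataclass
class AnalysisConfig:
    # DCE-MRI
    pe_threshold: float = 0.50          # PE >= threshold defines enhancing tumor
    ser_threshold: float = 1.1          # SER >= threshold defines washout
    hotspot_window: int = 3             # in-plane window size (odd)
    ser_epsilon: float = 1e-6           # relative guard for S2 ~ S0 degeneracy
    # DWI
    b_values: tuple[float, ...] = (0.0, 100.0, 800.0)  # s/mm^2
    adc_fit: str = "loglinear"          # "loglinear" or "nonlinear"
    # PET
    suv_window: tuple[float, float] = (30.0, 60.0)  # minutes post injection
    voi_volume_cc: float = 1.0
    conv_dt_min: float = 0.05           # convolution grid step for the 2TC model
    fit_vb: bool = False
    k_upper: float = 5.0                # upper bound for rate constants in fits
    glucose_unit: str = "mmol/L"
    # Statistics
    alpha: float = 0.05
    cox_unit_percent: float = 5.0       # HR reported per this % change
    km_metrics: tuple[str, ...] = (
        "k1",
        "mrfdg",
        "washout_volume",
        "peak_ser",
        "mrfdg_peak_ser",
    )

    def __post_init__(self) -> None:
        if self.hotspot_window % 2 != 1 or self.hotspot_window < 1:
            raise MpqError("hotspot window must be a positive odd integer")
        if not 0 < self.alpha < 1:
            raise MpqError("alpha must lie in (0, 1)")
        if self.suv_window[1] <= self.suv_window[0]:
            raise MpqError("SUV window must have positive duration")
        self.b_values = tuple(float(b) for b in self.b_values)
        self.suv_window = tuple(float(t) for t in self.suv_window)
        self.km_metrics = tuple(self.km_metrics)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["b_values"] = list(self.b_values)
        d["suv_window"] = list(self.suv_window)
        d["km_metrics"] = list(self.km_metrics)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MpqError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
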