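# mpq — multimodal PET/MRI quantification of neoadjuvant therapy response

`mpq` is a tested, reusable implementation of a serial multimodal
imaging analysis for breast cancer patients undergoing neoadjuvant
chemotherapy (NAC). It quantifies, per lesion and timepoint:

- **DCE-MRI enhancement kinetics** — percent enhancement
  `PE = (S1 − S0)/S0` and signal enhancement ratio
  `SER = (S1 − S0)/(S2 − S0)` from pre-contrast (S0), early 2-min (S1)
  and delayed 8-min (S2) T1-weighted phases; 3D tumor segmentation at
  PE ≥ 50%; hotspot peak PE/SER (highest mean over an in-plane 3×3
  tumor subregion); functional tumor volume (PE ≥ 50%, cc) and washout
  volume (SER ≥ 1.1, cc); longest dimension (mm).
- **DW-MRI diffusion** — voxel-wise monoexponential fit
  `S(b) = S(0)·exp(−b·ADC)` over b = 0, 100, 800 s/mm² and ROI-mean ADC.
- **Dynamic FDG-PET kinetics** — 30–60 min summed SUV images and
  SUVmax in a ~1 cc VOI; irreversible two-tissue-compartment fits of
  the tumor time-activity curve against a blood input function, giving
  K1 (delivery, mL/min/g), k2 (efflux, 1/min), k3 (trapping, 1/min),
  net flux `Ki = K1·k3/(k2 + k3)` and the FDG metabolic rate
  `MRFDG = Ki·[glucose]`.
- **Metabolism/perfusion mismatch** — MRFDG/peak PE, MRFDG/peak SER,
  MRFDG/K1, SUVmax/peak PE, SUVmax/peak SER.
- **Cohort statistics** — percent change from baseline at mid- and
  post-treatment; baseline Spearman correlations; Wilcoxon rank-sum
  comparisons of responders (residual cancer burden, RCB 0/I) versus
  non-responders (RCB II/III) with Benjamini–Hochberg correction;
  univariate Cox proportional-hazards regression of recurrence-free
  survival on percent change (hazard ratio per 5% change, Wald test);
  Kaplan–Meier curves dichotomized at the third quartile of percent
  change with log-rank tests.

Because serial clinical PET/MRI datasets are rarely shareable, the
package ships a first-class synthetic layer: digital tumor phantoms
with prescribed enhancement, diffusion and tracer kinetics, and cohort
generators whose group percent-change distributions and
recurrence-hazard linkage are parameterized the way the target study
population behaves. Every analysis stage is testable end-to-end
without external data.

## Worked example

```python
import numpy as np
from mpq import dce, pet, synth
from mpq.core import PatientPhysiology

spec = synth.PhantomSpec()  # 1 mm grid, radius-5 mm tumor: PE 0.8, SER 1.3
s0, s1, s2, _ = synth.make_dce_phantom(spec)
pe  = dce.compute_pe_map(s0, s1)
ser = dce.compute_ser_map(s0, s1, s2)
tumor = dce.segment_tumor(pe, threshold=0.50)
print(f"tumor voxels: {tumor.n_voxels}")
print(f"peak PE:  {dce.hotspot_peak(pe, tumor):.3f}")
print(f"peak SER: {dce.hotspot_peak(ser, tumor):.3f}")
print(f"FTV: {dce.functional_tumor_volume(pe, tumor):.3f} cc")
print(f"washout volume: {dce.washout_volume(ser, tumor):.3f} cc")

series, cp, mask = synth.make_pet_phantom(spec)   # 60-min dynamic series
tac = pet.extract_tac(series, mask)
fit = pet.fit_two_tissue(tac, cp, series.frame_start, series.frame_end)
phys = PatientPhysiology(300.0, 70.0, plasma_glucose=5.0)
print(f"K1 = {fit.params.k1:.4f} mL/min/g, k2 = {fit.params.k2:.4f}, "
      f"k3 = {fit.params.k3:.4f} 1/min")
print(f"Ki = {fit.ki:.4f} mL/min/g, "
      f"MRFDG = {pet.metabolic_rate_fdg(fit.params, phys):.4f}")
```

prints

```
tumor voxels: 515
peak PE:  0.800
peak SER: 1.300
FTV: 0.515 cc
washout volume: 0.515 cc
K1 = 0.1000 mL/min/g, k2 = 0.2000, k3 = 0.0500 1/min
Ki = 0.0200 mL/min/g, MRFDG = 0.1000
```

The noiseless phantom inverts exactly: segmentation recovers the
515-voxel digital sphere (0.515 cc at 1 mm³ voxels, all of it above the
washout threshold since the prescribed SER of 1.3 exceeds 1.1), and the
compartment fit recovers the prescribed K1/k2/k3 — so
Ki = 0.1·0.05/0.25 = 0.02 mL/min/g and, at 5 mmol/L plasma glucose,
MRFDG = 0.10.

A full study (images → lesion metrics → percent changes → statistics)
runs from a YAML manifest:

```bash
mpq run --manifest study/manifest.yaml --out results/
mpq analyze --cohort cohort.csv --out report/      # statistics only
mpq synth cohort --out cohort.csv --seed 7         # synthetic cohort
```

outputs include `lesion_metrics.csv`, `cohort.csv` (per-patient percent
changes and outcomes), responder-comparison and Cox summary tables,
Kaplan–Meier curve coordinates, and a provenance manifest; reruns with
the same inputs are bit-identical.

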