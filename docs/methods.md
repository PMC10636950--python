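# Methods

This note documents the models, conventions, numerical choices, and
known limitations of `mpq`. It describes what the code computes;
every empirical statement here is one the test suite or
`scripts/acceptance.py` computes itself.

## Image model and conventions

Volumes are 3D scalar arrays indexed `(slice, row, col)` with per-axis
spacing in mm. Clinical breast DCE-MRI is acquired axially with
anisotropic slice thickness, so every "3×3" neighborhood in the
package is in-plane (row × col within one slice), never through-plane.
All DCE phases and the DWI/PET frames of one exam are assumed
voxel-aligned; no inter-phase or inter-modality registration is
attempted (PET and MRI are acquired in different positions — supine
vs. prone — so only region-level, not voxel-level, correspondence is
meaningful). Units are declared metadata, never inferred; SUV assumes
a tissue density of 1 g/mL. Missing modalities leave metric fields
missing and per-metric analysis Ns shrink accordingly; there is no
imputation.

## DCE-MRI enhancement kinetics

Voxel-wise maps: `PE = (S1 − S0)/S0` (masked where S0 ≤ 0) and
`SER = (S1 − S0)/(S2 − S0)`, masked where `|S2 − S0| ≤ ε·max(S0, 1)`
with ε = 1e−6 — the ratio is undefined at the no-washout fixed point
and masking beats returning huge unstable values. Tumors are segmented
in 3D as 26-connected components of PE ≥ 0.50; lesion choice is by
user seed point when given, else the largest component (a
deterministic surrogate for manual lesion identification). The hotspot
peak of a map is the highest mean over an in-plane 3×3 window lying
*fully inside* the mask (a "tumor subregion" should contain only tumor
voxels); when no window fits — lesions under ~3 voxels across — the
single-voxel maximum is used and a warning logged. Functional tumor
volume is the volume of in-mask voxels with PE ≥ 0.50; washout volume
the volume of in-mask voxels with SER ≥ 1.1. Computing washout within
the segmented tumor (rather than the whole breast) avoids counting
vascular/background voxels and gives the invariant
`washout ≤ FTV`, which the tests exploit. Longest dimension is the
maximum pairwise distance between mask voxel centers; above 400 voxels
the search is restricted to convex-hull vertices (provably containing
the diametral pair), with a brute-force fallback for degenerate hulls.

Raw (unsmoothed) PE voxels feed the FTV threshold, and hotspot windows
for peak SER are restricted to SER-valid voxels.

## DW-MRI

Per-voxel ordinary least squares on `ln S(b) = ln S(0) − b·ADC`, using
all supplied b-values (default 0, 100, 800 s/mm²). The log-linear fit
is deterministic, has a closed two-point form (tested against it), and
is the conventional reading of "monoexponential"; a nonlinear option
exists behind a flag. Whether b = 100 should be excluded for perfusion
suppression is protocol-dependent; the b-value list is configurable.
Voxels with any non-positive signal are flagged invalid (NaN), never
silently zeroed; ROI means run over valid voxels and report the
exclusion count.

## Dynamic FDG-PET

The kinetic model is the irreversible two-tissue compartment model
(k4 = 0, standard for FDG over 60 min):

    dC1/dt = K1·Cp − (k2 + k3)·C1,   dC2/dt = k3·C1

with closed-form impulse response
`h(t) = K1·(k3 + k2·e^{−(k2+k3)t})/(k2+k3)`; the measured curve is
`(1 − Vb)·(h ⊛ Cp) + Vb·Cp`, frame-averaged over each acquisition
interval. Vb defaults to 0 and can be fitted. The convolution runs on
a uniform 0.05-min grid with linear interpolation of Cp and a
trapezoid-rule correction (second-order in dt); tests verify agreement
with a 10×-finer-grid quadrature and with a direct ODE integration to
< 0.5% of peak.

Fitting is bounded trust-region nonlinear least squares with weights
`sqrt(frame duration / max(|activity|, floor))` — an approximation to
count statistics — started from a fixed 8-point lattice of plausible
breast-FDG parameter sets; the best weighted residual wins, ties going
to the earlier start. No randomness enters the fit. The macro-parameter
`Ki = K1·k3/(k2+k3)` is identifiable even when k2/k3 trade off, and is
always recomputed from the micro-parameters, never stored. A TAC that
is identically zero returns a flagged degenerate result (K1 = 0)
rather than raising.

SUV images are duration-weighted means of the frames inside the 30–60
min window, scaled by body weight / injected dose. SUVmax is the
maximum voxel in a sphere of ~1 cc; the sphere center defaults to the
centroid of the connected ≥50%-of-max uptake region containing the
hottest voxel — a deterministic surrogate for manually drawing a VOI
around the hottest pixels that is robust to single-voxel noise.
`MRFDG = Ki·[glucose]` with no lumped-constant correction; glucose
concentration units are declared and never converted silently.

## Statistics

Percent change is `100·(x_t − x_0)/x_0`, missing when the baseline is
missing or zero. Mismatch ratios (MRFDG/peak PE, MRFDG/peak SER,
MRFDG/K1, SUVmax/peak PE, SUVmax/peak SER) go missing only where their
own denominator is missing or non-positive.

- Spearman correlations use average ranks and the t-approximation,
  with pairwise-complete deletion.
- Wilcoxon rank-sum comparisons (responders RCB 0/I vs. non-responders
  RCB II/III; patients progressing to metastasis before surgery count
  as non-responders) use the exact null distribution for combined
  n ≤ 20 without ties, else the normal approximation with continuity
  and tie corrections. Two-sided throughout, α = 0.05.
- Benjamini–Hochberg adjustment is applied within one family per
  (analysis type × timepoint) — e.g. all metrics' mid-treatment
  Wilcoxon p-values form one family. The family structure is
  configurable.
- Cox proportional-hazards regressions are univariate, on percent
  change scaled to 5%-change units, with Efron tie handling and Wald
  tests/CIs (the implementation reproduces R `survival::coxph` to
  ≥ 7 significant digits on a frozen fixture). Monotone-likelihood and
  degenerate inputs return flagged results.
- Kaplan–Meier analyses dichotomize at the third quartile (linear
  interpolation between order statistics) of percent change. Since
  responding tumors mostly show negative changes, the group with
  change ≤ Q3 is labelled "larger decrease"; both curves carry
  explicit labels so the direction is never implicit. Log-rank
  chi-squares are checked against R `survival::survdiff`.

The full grid (`run_full_analysis`) is deterministic given a cohort
table and degrades gracefully: single-patient cohorts, no events, or
constant covariates produce flagged results and notes, not exceptions.

## Synthetic data

The image layer builds spherical-tumor phantoms whose construction
inverts the measurement models exactly (S1 = S0(1+PE),
S2 = S0 + (S1−S0)/SER; S(b) = S0·e^{−b·ADC}; PET frames from the same
2TC forward model the fitter uses). The default phantom is a 1-mm grid
with a radius-5 mm tumor — exactly 515 voxel centers — with tumor
PE 0.8 / SER 1.3 / ADC 1.0×10⁻³ mm²/s / (K1, k2, k3) =
(0.10, 0.20, 0.05) over a background of PE 0.1 / SER 0.8 /
ADC 2.0×10⁻³ / (0.02, 0.40, 0.002); per-patient kinetic truths are
typical breast-FDG literature scales, a declared stand-in since no
per-patient parameter values are published. The arterial input is a
Feng-type tri-exponential, smooth and integrable so oracle checks have
closed quadratures. Noise models are explicit options: relative
Gaussian for DCE, Gaussian or Rician for DWI, and Gaussian with
variance ∝ activity/frame-duration for PET (the standard
reconstruction-domain approximation). Phantoms emulate contrast,
decay, and kinetics only — no anatomy, partial volume, motion, or
scanner physics — so passing recovery tests demonstrate correctness of
the estimators, not clinical robustness.

The cohort layer draws the responder flag first (defaults 11
responders / 24 non-responders, mirroring the target study design) and
conditions metrics on it: percent changes are Normal(group mean, group
SD) per metric and timepoint, with defaults set to the published
group-level mean (SD) values of the serial NAC imaging study this
package operationalizes (e.g. mid-treatment peak PE −31.1 (12.6)% in
responders vs. −15.1 (28.0)%). Recurrence times follow an exponential
proportional-hazards model whose log-hazard is linear in (percent
change)/5, centered at the population mean so the marginal event rate
stays near the base hazard (0.03/year by default; default linkage
coefficients correspond to hazard ratios 1.03–1.38 per 5% change for
K1, MRFDG, washout volume and peak SER); censoring is uniform over a
1.1–9.8-year follow-up window. Baseline metric values, used only by
the baseline correlation analyses, are independent lognormals at
plausible breast-tumor scales. The generator draws metric changes
directly rather than via simulated images, so the statistics layer is
testable at cohort sizes (up to 10⁴ per group in the
law-of-large-numbers test) that image simulation could not reach.

The image-level study fixture (`make_synthetic_study`) writes 6
patients × 3 timepoints of phantoms plus a YAML manifest; tumor radii
stay ≥ 6.6 mm so the 1 cc VOI (radius 6.2 mm) remains inside the
lesion, and response is expressed through declining enhancement,
trapping and delivery. One patient is MRI-only to exercise per-metric
missingness.

## Problem sizes and calibration checks

The acceptance script and test suite use deliberately desk-scale
problem sizes chosen to give stable Monte-Carlo estimates: 1000 noisy
voxels for ADC bias, a 27-point (K1, k2, k3) grid plus 30–50 noisy
replicates for kinetic recovery, 400–1000 null cohorts of 30/30 for
test calibration, 200–500 cohorts of 200/group for detection power,
and 30–50 cohorts of 300 for hazard-ratio recovery. Calibration
assertions allow ±1.5 percentage points around the 5% level (binomial
Monte-Carlo error at these replicate counts); the empirical BH false
discovery rate under the global null has expectation equal to the
nominal level, so it is checked against nominal plus two standard
errors rather than with a strict inequality.

## Known limitations

- No pharmacokinetic (Tofts-type) DCE modeling: three post-contrast
  phases cannot support it.
- No Patlak cross-check, metabolite or partial-volume correction of
  the input function, and no left-ventricle VOI auto-detection; the
  blood curve is a user input.
- k2 and k3 are individually far less stable than Ki/K1 under noise
  (the tests document this with a much looser bound).
- Whether clinical SER analyses include a blood-volume term or exclude
  b = 100 from ADC fits varies by site; both choices are configurable
  but defaults follow the conventions above.
- Mean/median ROI summaries ignore intratumoral heterogeneity.
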