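# Methods

This note documents the models, estimators and numerical choices behind
`aisquant`, and what the synthetic-data results do and do not establish
about real recordings.

## AIS morphometry

**Model.** An AIS appears in an immunofluorescence profile as a plateau of
near-constant labeling density between its start and end, blurred by the
microscope point-spread function (PSF) and corrupted by additive noise.
The generator renders exactly this: a unit plateau on `[start, end]`
convolved analytically with a Gaussian of width `psf_sigma_um`
(erf-ramp edges), plus i.i.d. Gaussian noise, clipped at zero (photon
counts are non-negative).  Images render the same longitudinal profile as
a tube with Gaussian cross-section (default 0.4 µm), so profile extraction
along the true path reproduces the 1D generator.

**Measurement.** Profiles are extracted from max-intensity projections by
resampling the traced polyline at one-pixel arc-length steps with bilinear
interpolation; positions are arc length from the first vertex, which marks
the soma edge (so the detected start position is also the AIS onset
distance).  After a centered moving average (default 1.0 µm, edges handled
by window shrinking), start and end are the outermost positions sustaining
intensity ≥ `bg + θ·(max − bg)` for at least 0.5 µm, where `bg` is the 5th
percentile of the profile.  θ defaults to 0.20, the midpoint of the
accepted 10–30% range; per-dataset override is allowed because staining
quality legitimately varies.  The relative threshold makes all outputs
invariant to intensity scaling and the background estimate makes them
robust to nonzero baselines.

**Sub-pixel refinement.** Crossings are refined by linear interpolation
between the bracketing samples — but only when the edge is *resolved*
(the one-pixel jump is at most half the dynamic range).  An aliased edge
(e.g. a sharp unblurred plateau) snaps to the suprathreshold sample: a
linear model across a discontinuity would systematically place the
boundary (1−θ) pixels outside the structure.  With this rule, unblurred
noiseless plateaus are recovered to within one pixel and blurred edges to
within the linearization error of the erf ramp (≪ 0.1 µm).

**What "length" means here.** For a blurred plateau the θ-crossing sits
`psf_sigma·|Φ⁻¹(θ)|` outside each true edge (≈ 0.42 µm per side at
θ = 0.2, σ = 0.5 µm).  This is a property of the threshold convention, not
an estimator defect; accuracy statements in the tests are therefore made
against the θ-crossing positions of the ideal noiseless profile (computed
by an independent dense-grid oracle), while the plateau itself is the
reference only in the unblurred case.

## Synthetic length cohorts

Cohort presets model AIS length populations as truncated Normals on
[5, 70] µm.  The location/scale pairs are calibrated to published
distribution summaries of developmental deprivation cohorts — medians
30.8/35.8 µm (P15 control/deprived) and 25.6/31.0 µm (P21), with scale
derived from the printed full widths at half maximum via
σ = FWHM / (2√(2 ln 2)): 5.054, 10.744, 4.157 and 4.612 µm respectively.
The truncation bound accommodates the long upper tail (individual AIS
approaching 60 µm) without nonphysical values.  The enriched-environment
pair (24.0 vs 21.0 µm, σ = 4.0) encodes the ~3 µm rapid shortening of the
stimulated hemisphere; c-Fos⁺ (recently active) cells are modeled as a
−3 µm location shift of their stratum.  A Normal is the minimal model
consistent with a printed median and FWHM; this is a calibration choice,
not a claim about the real data's shape (the real deprived distribution is
visibly right-skewed, which the symmetric preset does not reproduce).

Simulated animals add a shared per-animal location offset (default 1 µm SD
in the paired design), so paired hemisphere analyses genuinely benefit
from within-animal pairing.  Each animal contributes 100 AIS, matching the
≥ 100-per-animal sampling rule that the aggregation utilities enforce.

## Stylized action potentials

The spike generator is *not* a conductance model; it is a piecewise
analytic waveform whose measured features are exact by construction, which
is what a feature-extraction test bed needs.  dV/dt over the upstroke is
piecewise linear in time: a lead-in ramp reaching 50 V/s exactly when the
voltage reaches the nominal threshold, short plateaus at the two requested
phase-plane rates (axonal then somatic component), and a final ramp to
zero at the peak; the repolarization is linear at the rate that makes the
half-width (width at the mid voltage between threshold and peak) exact.
All pre-peak knots sit on the 50 kHz sample grid, so centered finite
differences recover the threshold voltage at a sample and the plateau
rates exactly; the only discretization errors are the off-grid peak
(< 0.2 mV) and the interpolated mid-voltage crossings (≪ 1 sample).

Sub-rheobase steps charge exponentially toward `v_rest + I·R_N`
(τ = 5 ms, R_N = 300 MΩ defaults); spiking steps use a stylized
depolarized plateau 10 mV below threshold between spikes.  Long-step spike
counts follow a supplied monotone f(I) lookup (counts are f·duration
rounded half-up; exact when integral), so I–f ground truth is exact.  The
simulated AIS-length → rheobase coupling is linear,
`rheobase = 400 − 5·length` pA, giving ~50 pA per 10 µm — the scale of the
deprivation effect; the slope is configurable because no regression slope
is published.  The acquisition Bessel-filter chain is not emulated.

## Feature extraction conventions

* dV/dt is the centered finite difference at the native rate, unsmoothed;
  the 50 V/s criterion is compared with a 1e-6 tolerance so exact-slope
  breaks are not lost to rounding.
* "Reliably elicited" for the current threshold is operationalized as
  monotone persistence: the smallest step that spikes while every larger
  recorded step also spikes.  A single-trial protocol admits no
  repeat-based definition; isolated sub-threshold spikes produce a
  diagnostic error instead of a guess.
* Phase-plane peaks use a 10 V/s prominence floor; unresolved (mono-phasic)
  shapes return the single maximum for both components with a flag rather
  than a fabricated split.
* Steady state for R_N is the mean over the final 20% of the step; the
  baseline is the 50 ms pre-step mean; sweeps containing an AP are
  excluded from the V–I fit.  R_s above 30 MΩ sets an exclusion flag.
* PSC detection is Clements–Bekkers scaled-template matching with a
  biexponential kernel (0.5 / 5 ms defaults) and criterion 3.0, where the
  criterion is the fitted scale divided by the residual SD (an SNR-like
  quantity — at 3.0 the white-noise false-positive rate is negligible,
  which a t-statistic normalization would not give).  One event is taken
  per contiguous supra-criterion region; a small relative floor
  (10⁻³ of the trace's dynamic range) on the residual SD keeps noiseless
  traces from flagging machine-epsilon tails.  The original analysis used
  a proprietary event detector; these are this package's own parameters.

## Junction potential

The generalized Henderson equation is evaluated from free-ion
decompositions of the salt recipes: strong salts fully dissociated, HEPES
contributing its anionic fraction `1/(1+10^(pKa−pH))` (pKa 7.48), Mg-ATP
and Na₂-GTP dissociated into their table ions, glucose neutral.  The
mobility table stores limiting equivalent conductivities (S cm² eq⁻¹,
25 °C); only ratios enter the equation.  The sign convention is
pipette-minus-bath, and a helper subtracts the value from recorded
potentials.  For the standard 140 mM K-gluconate pipette against
bicarbonate ACSF the computation gives ≈ −15.2 mV at 298.15 K — the
expected scale for gluconate-based internals, dominated by the mobility
mismatch between K⁺ (73.5) and gluconate⁻ (24.3).  The result is
insensitive (< 0.5 mV) to the treatment of the minor species (ATP/EGTA
complexation, phosphate speciation, ±3 K).  Electroneutrality violations
above 5% of total charge warn but do not abort, since published recipes
omit the titrant.

## Statistics

* Two-group comparisons gate on Shapiro–Wilk at α = 0.05 per group:
  both normal → two-sided t-test (paired or unpaired), otherwise
  Mann–Whitney U (Wilcoxon signed-rank when paired).  The branch taken is
  reported.  Constant samples are routed to the non-parametric branch.
* Two-way ANOVA uses Type II sums of squares (groups are near-balanced;
  Type II is invariant to cell-count imbalance under the no-interaction
  null).  Post-hocs are pooled-error t-tests on user-specified cell pairs
  with Sidak (`1−(1−p)^m`) or step-down Holm–Sidak adjustment.  Repeated-
  measures designs are approximated by per-animal paired differences plus
  the gated paired test rather than a full RM-ANOVA; studentized-range
  (Tukey/Dunnett) post-hocs are mapped onto the Sidak family.
* The two-sample KS test enumerates all C(nx+ny, nx) label assignments
  (vectorized) when both n ≤ 10 — with ties handled by evaluating the CDF
  difference only at tie-group boundaries — and uses the asymptotic
  Kolmogorov distribution otherwise.  Distribution-shift tests pool AIS
  across animals, which ignores within-animal clustering; the per-animal
  aggregation path exists precisely because pooled KS p-values on
  clustered data overstate certainty.
* FWHM is measured on a Gaussian-KDE (Silverman bandwidth
  `0.9·min(sd, IQR/1.349)·n^(−1/5)`) evaluated on a 0.1 µm grid, between
  the outermost linear-interpolated half-max crossings; multimodality at
  half height is flagged.  The KDE convolution widens the curve by
  ~σ_bw²/2σ relative to the underlying density (≈ +3% at n = 600), which
  is inherent to any smoothed length-frequency curve and shrinks as
  n^(−2/5); a 2.5 µm histogram variant is available for sensitivity
  checks.

## Problem sizes and determinism

All generators take explicit integer seeds; the pipeline derives
per-stage child seeds by hashing `seed:stage`, so stages are
independently reproducible and identical configurations produce
byte-identical outputs.  The test suite sizes its Monte-Carlo checks for
a single CPU: 10⁴ null simulations for the type-I error check, 200 seeds
for boundary-detection accuracy, 20 seeds for cohort calibration and the
end-to-end distribution-shift run, 60 random parameter draws for AP
feature recovery, 10 seeds × 30 s traces (10 kHz) for PSC recall, 50
random designs for the ANOVA oracle.  The acceptance script uses 20
replicate 600-AIS cohorts per distribution summary and one 6-animal
paired cohort.

## Known limitations

* No automatic AIS tracing: paths are user-supplied (or synthetic), as in
  the human-traced workflow the method mirrors.
* The stylized AP waveform cannot probe detection robustness to
  biophysical waveform diversity (bursting, depolarization block).
* Symmetric length presets understate the skew of strongly deprived
  populations.
* The Henderson computation treats weak-acid speciation with a fixed-pKa
  table rather than a full activity-corrected equilibrium model.
* Pooled KS tests on clustered cohort data overstate significance;
  per-animal tests are the conservative alternative offered.
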