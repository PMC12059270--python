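# Methods

`radstab` studies how simultaneous-multislice (SMS) acceleration and the
choice of 2D versus 3D tumor segmentation affect the stability of radiomics
features computed on diffusion parametric maps (ADC, IVIM D/D*/f, DKI
MD/MK), using fully synthetic multi-b-value DWI cohorts with known ground
truth. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic world does and does not establish.

## Signal models

All fits operate on signals normalized to S(b=0):

* **ADC** (mono-exponential, two points): `ADC = ln(S0/S800) / 800`, from the
  b = 0 and b = 800 s/mm² volumes.
* **IVIM** (bi-exponential, 9 b-values ≤ 800 s/mm²):
  `S(b)/S0 = (1−f)·exp(−b·D) + f·exp(−b·(D+D*))`, with tissue diffusivity D,
  pseudo-diffusivity D*, and perfusion fraction f. The pseudo-diffusion
  compartment decays with D + D*, the standard convention.
* **DKI** (quadratic-in-b, 6 b-values {0, 200, 400, 800, 1500, 2000}):
  `S(b)/S0 = exp(−b·MD + b²·MD²·MK/6)`.
* **Combined forward model** (cohort default): perfusion compartment plus a
  kurtosis tissue compartment,
  `S/S0 = f·exp(−b·D*) + (1−f)·exp(−b·MD + b²·MD²·MK/6)`, so that all six
  fitted maps are meaningful on one phantom.

## Fitting

IVIM uses the classical segmented initialization — log-linear D and
intercept-derived f over b ≥ 200 s/mm² (the smallest b acquired with more
than one average), D* from a log-linear fit of the low-b residue — followed
by a bounded full nonlinear least-squares refinement (default on). DKI is
initialized by linear least squares in (b, b²) and refined the same way.

The refinement is a projected Gauss–Newton iteration with a small Levenberg
ridge, per-voxel step halving, and an active set that retires converged
voxels; it is vectorized across all voxels of a series at once, which is
what keeps whole-cohort runs on one CPU within minutes. Steps are accepted
only when they reduce the SSE, so a voxel for which no refinement step helps
keeps its segmented estimate (the documented fallback). On noiseless
forward signals the refinement recovers IVIM parameters to ~1e-9 relative
and DKI parameters to machine precision.

Bounds (physiological, also the divergence guard at low SNR):
D ∈ [1e-5, 4e-3], D* ∈ [1e-5, 0.5], f ∈ [0, 1], MD ∈ [1e-5, 4e-3] (mm²/s),
MK ∈ [0, 3]. Goodness of fit is R² = 1 − SS_res/SS_tot per voxel and per
model. The fit-quality exclusion rule (R² < 0.8) operates on two levels,
both configurable: failing voxels are dropped from the fit mask, and a
subject-level exclusion flag is raised when the ROI-median R² of either
model is below threshold.

## Synthetic cohort

One subject = a 64×64×24 grid at 3.0×2.8×4.4 mm (matching a 380×356 mm FOV
at a 128 matrix downsampled 2×, 24 slices of 4+0.4 mm) containing one
ellipsoidal lesion in homogeneous background tissue. Default lesion
parameter ranges (sampled per subject) are at cervical-tumor scales:
S0 ∈ [190, 230] a.u., D ∈ [0.7, 1.1]×10⁻³, D* ∈ [7, 15]×10⁻³,
MD ∈ [1.0, 1.5]×10⁻³ mm²/s, f ∈ [0.08, 0.18], MK ∈ [0.7, 1.0]. Background:
D 1.6×10⁻³, MD 1.7×10⁻³ mm²/s, f 0.05, MK 0.4, S0 170.

Within-lesion heterogeneity is a multiplicative Gaussian-blob texture
(40 blobs, correlation length 3 voxels, amplitude 0.12 = maximum fractional
deviation), centered so the lesion mean equals the nominal parameter value,
and clipped to ±amplitude. High-stage lesions get the amplitude multiplied
by 1.6 and radii by 1.3, so gray-level-nonuniformity-type features genuinely
separate the two stage groups; the default cohort is 12 low + 28 high.

SMS acceleration is modelled with exactly two knobs per sequence:
T1-saturation scaling `1 − exp(−TR/T1)` using the protocol TRs
(4700/2500/2000 ms for AF 1/2/3) with T1 = 1500 ms, and a Rician noise-scale
multiplier (1.0/1.1/1.3). Slice leakage and reconstruction artifacts are
deliberately out of scope. Noise is Rician: each of the per-b `n_averages`
acquisitions is an independent magnitude image
`sqrt((S+n_r)² + n_i²)`, and the averages are averaged as magnitudes — this
preserves the low-SNR Rician bias that drives D*/f instability.

**Noise-scale calibration.** The noise scale σ is the one free parameter the
acquisition tables do not pin down; it was calibrated once (σ ∈ {3, 5, 6, 7}
swept on three master seeds) so that the default cohort reproduces the
qualitative image-quality ordering S1 ≈ S2 > S3 — S3 significantly worse
than both in the Dunn–Bonferroni post hoc test, S1 vs S2 not — and then
frozen at σ = 5.0. At σ = 3 the S2–S3 contrast is too weak; at σ ≥ 6 the
S1–S2 contrast becomes significant (wrong ordering) and bound clipping at
very low SNR artificially stabilizes the D*/f maps.

All randomness derives from a single master seed through fixed
`SeedSequence` key tuples (seed, subject index, sequence index, purpose), so
every artifact is a pure function of (config, seed).

## Features

93 features per map per ROI mode: 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM, 14 GLDM, with IBSI/pyradiomics-consistent definitions,
each family verified against an independent brute-force enumeration.
Intensities are discretized per map to a fixed bin count (32) within the
ROI; a fixed bin width is inappropriate here because the six maps live on
heterogeneous physical scales (10⁻³ mm²/s versus unitless fractions).
2D mode uses the axial slice with maximal lesion area (ties → lowest index),
4 in-plane directions and 8-connectivity; 3D uses 13 unique directions and
26-connectivity. Matrices are normalized per direction and features averaged
unweighted. Gray levels are 1-based; distances are in voxels. The GLDM
dependence size counts the center voxel plus its dependent neighbors
(|level difference| ≤ α, α = 0), so size-weighted features never divide by
zero. Degenerate features (e.g. any texture feature of a single-voxel ROI)
are returned as 0 with an explicit flag, never as silent NaN; undefined
ratio denominators use an ε = 10⁻⁶ guard (NGTDM Coarseness → 10⁶).

## Stability and screening statistics

* **CCC** (Lin): `2ρσxσy / (σx² + σy² + (μx−μy)²)` with population (1/n)
  moments, computed across subjects for S1–S2 and S1–S3. Identical constant
  vectors → 1; a single constant vector → 0 (flagged).
* **COV**: sample SD (n−1) across the three sequences divided by |mean|,
  computed per subject and then averaged over subjects with defined values.
  The within-subject form measures acquisition-induced variation rather than
  biological between-subject variation; |mean| < 10⁻¹²·scale is undefined.
* **Categories** (half-open, aligned with the stable rule): CCC — excellent
  > 0.9, good (0.75, 0.9], moderate (0.5, 0.75], poor ≤ 0.5; COV — excellent
  < 0.05, good [0.05, 0.1], moderate (0.1, 0.2], poor > 0.2.
* **Stable**: CCC > 0.9 in *both* comparisons and mean COV ≤ 0.1
  (conservative reading; an S1–S2-only mode is provided).
* **Staging screen** (analysis sequence S2 by default): Shapiro–Wilk-routed
  Welch t-test / Mann–Whitney U (exact when min group ≤ 8 and no ties), then
  an ICC(2,1) (two-way random, absolute agreement, single measurement) gate
  at 0.75 against features re-extracted from morphologically perturbed masks
  (1-voxel in-plane erosion/dilation, seeded — the second-reader emulation),
  then ROC AUC with high stage as the fixed positive class. No
  multiple-testing correction, matching common practice in this literature;
  the run report prints the caveat.
* **Image quality**: SNR = SI/SD and CNR within-ROI statistics on the b=800
  volume, tumor ROI on the largest-area slice and a background reference
  ("muscle") ROI; triplicate measurement emulated by 1-voxel jittered mask
  copies. Friedman test via scipy; Dunn–Bonferroni post hoc implemented from
  rank sums (z = Δmean-rank / sqrt(k(k+1)/6n), ×3, capped at 1) so the
  rank-arithmetic oracle is exact.

## What a green test establishes — and what it does not

The generator emulates parameter heterogeneity, Rician noise, signal
averaging, T1 saturation and noise amplification under SMS, and
inter-observer mask perturbation. It does **not** emulate motion, eddy
currents, susceptibility artifacts, slice leakage, k-space reconstruction,
or model misfit (the simulated tissue signal follows the kurtosis model
exactly). Consequences observed on the default cohort over 10 master seeds:

* Stability degrades with acceleration (mean CCC S1–S3 < S1–S2), the D* and
  f maps are by far the least stable, 3D features are at least as stable as
  2D, and the image-quality ordering S1 ≈ S2 > S3 is reproduced — each in at
  least 8 of the 10 seeds.
* The ADC map attains the maximum stable-feature proportion in only 5/10
  seeds: the MD map ties or slightly exceeds it otherwise. This is an honest
  discrepancy of the synthetic world: with the tissue compartment following
  the kurtosis model exactly and the high-b points carrying 4 and 6
  averages, the DKI MD estimate is nearly as noise-robust as the closed-form
  ADC. The much larger ADC-versus-MD stability gap reported on patient data
  likely also reflects motion and model misfit at high b, which are outside
  this model's scope. The corresponding acceptance test is left failing
  rather than weakening the criterion or re-tuning the frozen generator.

## Performance notes

Simulation and fitting are vectorized over voxels; the nonlinear refinement
retires converged voxels each iteration. Noise draws use float32 (generation
dominates simulation cost; the precision is irrelevant at these SNRs). One
40-subject cohort (120 series, 133 920 feature values, 1 116 stability
records) runs in ~70 s on one CPU.

## Known limitations

* No motion/artifact model (see above) — the main reason the ADC-dominance
  property is not fully reproduced.
* The acquisition-table values (b scheme, averages, TRs) are fixed to one
  pelvic protocol; other protocols require a custom `BValueScheme`.
* COV interpretation: the "average of the combination" in the ratio is
  resolved as the within-subject mean across sequences; other readings
  (pooled mean) change absolute COV values but not orderings.
* Feature definitions target IBSI consistency but are not IBSI-certified;
  resampling, wavelet/LoG filtering and shape features are out of scope.
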