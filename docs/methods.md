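# Methods

`ponsmrsi` implements a tissue-composition-aware analysis of multi-voxel
proton MR spectroscopy (chemical shift imaging, CSI) of the pontine
brainstem, together with a synthetic-cohort generator that emulates the data
structure such a study produces.  This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic data do and do not establish.

## The measurement model

Each subject contributes 16 CSI voxels on a fixed grid: six in the right
pons (R1–R6), six in the left pons (L1–L6) and four cerebellar reference
voxels (C1–C4).  Row numbering follows the gray-matter gradient: rows 5/6
are white-matter-rich (~12 %GM of the brain tissue sampled), rows 3/4
intermediate (~33%), rows 1/2 gray-matter-rich (~63%), and the cerebellar
voxels predominantly gray matter (~90%).

Voxel composition is summarized by

    %GM  = 100·GM/(GM + WM),        %CSF = 100·CSF/(GM + WM + CSF),

and a metabolite amplitude S0 measured in a voxel containing a CSF fraction
f = %CSF/100 is corrected for the signal-free CSF partial volume as

    S = S0 / (1 − f).

The correction is implemented without a global scale constant: only relative
and ratio quantities are used downstream, and the defining property — that
the correction exactly inverts a CSF dilution and cancels in within-voxel
ratios — fixes it up to that constant.  Note that the correction does *not*
cancel in cross-voxel ratios (pons value over cerebellar reference), which
is why it is applied before cerebellar normalization.

Amplitudes are generated (and modeled) as tissue-fraction-weighted mixtures
of pure-tissue concentrations,

    S0 = (g·C_GM + (1−g)·C_WM) · (1 − f) + ε,   g = %GM/100,   ε ~ N(0, σ²),

so the CSF correction is the exact inverse of the generative dilution in
expectation, and the NAA/tCr ratio is an exact rational function of
composition on noiseless data.

## Spectral engine

The spectral stage is a deliberately transparent linear-combination fitter,
not a reproduction of any proprietary quantification package.  Spectra are
sums of unit-height Lorentzians on a 0.5–4.5 ppm axis (512 points, 1.5 T
conventions) with amplitudes `concentration × protons × exp(−TE/T2)`;
fitting is non-negative linear least squares of the real part against the
noiseless basis.  Relative Cramér–Rao lower bounds are
`100·σ̂·sqrt(diag((BᵀB)⁻¹))/amplitude` with σ̂ the degrees-of-freedom-
corrected residual SD, capped at 999% so near-zero amplitudes stay finite
but always fail quality control.

Creatine and phosphocreatine co-resonate near 3.03 ppm and are separable
only through their transverse relaxation times (T2 ≈ 309 ms for Cr, 117 ms
for PCr).  At the default echo time TE = 135 ms the observed total-creatine
amplitude is `Cr·e^{−135/309} + PCr·e^{−135/117} ≈ 0.646·Cr + 0.315·PCr`:
weighted toward Cr, and strictly decreasing in TE.  The fitter therefore
pools the pair into one tCr basis column; the Cr:PCr split exists only on
the simulation side, which mirrors the physical situation that a shift of
the Cr:PCr equilibrium changes the apparent tCr peak at constant total
creatine.  Attempting to fit the two pools as separate columns raises a
collinearity error naming the pair.  myo-inositol is excluded from the
basis: its J-coupled multiplet yields too little signal at this TE to
quantify.  The NAA T2 default (350 ms) is a typical 1.5 T value; the
acquisition defaults (TE 135 ms, TR 1750 ms) match the CSI protocol being
emulated.

## Quality control

A metabolite value whose reported relative CRLB strictly exceeds 20% is
voided (the boundary value 20.0% is retained — exclusion requires "greater
than").  Rejection voids only that metabolite in that voxel; the subject and
their other voxels remain, and group statistics use available cases per
voxel.  The generator reports CRLBs as `100·σ·k/amplitude` (k = 1 by
default, matching a ~13% tCr / ~5% NAA regime at the default noise), plus a
3.5% chance of an inflated draw from U(25, 50)% that emulates occasional
unusable fits; this puts the filter's operating point at the few-percent
rejection rates typical of pontine CSI, and NAA bounds below tCr bounds
(the NAA peak is larger, and the tCr peak additionally T2-attenuated).

## Ratios and the pure-tissue projection

Per subject, pons NAA and tCr (CSF-corrected) are divided by the mean of
the subject's surviving cerebellar values, giving NAA/NAA_Cb and tCr/tCr_Cb;
the within-subject reference makes the ratios invariant to any global
per-subject scaling such as coil loading.  If all four cerebellar values of
a metabolite are rejected the subject's normalized ratios for that
metabolite are missing (logged), never imputed.

Because both metabolites are linear in the white-matter fraction
fWM ∈ [0, 1] of the tissue sampled, NAA/tCr is a rational linear/linear
function of fWM.  It is fitted per group as

    r(f) = (α + β·f) / (1 + γ·f),

a parameterization whose denominator is positive on [0, 1] whenever the
GM-side denominator is (γ > −1), with α the pure-GM endpoint directly.  The
fit is nonlinear least squares initialized from the ordinary linear fit
(which remains available as a fallback method); endpoints at f = 0 and
f = 1 carry delta-method standard errors.  On noiseless mixture data the fit
is exact, recovering the generator's pure-tissue ratios to machine
precision.  Between-group endpoint differences are assessed by a
nonparametric bootstrap that resamples *subjects* (default 2000 draws,
seeded), respecting the within-subject correlation of the 16 voxels; the
pooled-voxel fit with subject-level bootstrap is a design choice, since
subject-wise curve fitting from 16 points per subject is poorly conditioned
in the cerebellum-free groups of voxels.

## Group statistics

Per pons voxel, the ratio outcome is regressed on group with %GM as
covariate (optionally age as a second covariate); pairwise contrasts
(each patient group vs control, and low vs high fatigue) are taken from the
full three-group model so they share one covariate-adjusted error term.  A
constant covariate is dropped with a warning, falling back to the plain
one-way comparison.  Raw contrast p-values are corrected per outcome and
contrast across the 12 pons voxels with Benjamini–Hochberg (the cerebellar
voxels are reference-only and not part of the family); significance flags
derive from the adjusted values at the 0.05 level only.

Clinical comparisons between the fatigue groups use the Mann–Whitney test:
exact by full enumeration of all C(n+m, n) assignments of the mid-ranked
pooled sample when both groups have ≤ 8 observations (ties handled without
approximation; identical samples give p = 1 exactly), and the tie-corrected
normal approximation otherwise — the switch point brackets the group sizes
(7, 10) this design produces.  Correlations are Pearson product-moment with
the two-sided t-transform p-value.

## Synthetic cohort defaults (the study conditions)

* Group sizes 15 / 7 / 10 (control / low fatigue / high fatigue) — the
  analyzed sample after motion rejections, not the recruited one.
* Per-voxel %GM means and SDs follow the observed control gradient
  (R6 12.3 ± 5.7 … C2 94.3 ± 4.0), drawn as truncated normals in [0, 100].
* Pure-tissue amplitudes gm = {NAA 1.10, tCr 1.00}, wm = {NAA 2.00,
  tCr 0.73}: noiseless NAA/tCr runs from 1.10 (pure GM) to 2.74 (pure WM),
  reproducing the observed voxel-ratio scale (~2.5 in WM-rich pons rows,
  ~1.2 in cerebellum), with tCr higher in GM per the glial-density gradient.
* CSF fractions uniform in (0.02, 0.15) for pons and (0.05, 0.25) for
  cerebellum — plausible ranges for peri-ventricular pons and folial
  cerebellum; the study itself reports none.
* Amplitude noise σ = 0.08, giving ratio SDs ≈ 0.35 at r ≈ 2.5 and the CRLB
  regime above.
* Clinical distributions per group: age, FSS truncated normals at the
  observed means/SDs/ranges; EDSS uniform on the 0.5-step grid within the
  observed range; lesion load log-uniform within the observed range;
  controls carry no EDSS or lesion values.  FSS truncation keeps every
  group on its own side of the >36 fatigue cutoff, as the observed ranges do.
* Default group effect: tCr ×1.25 in high-fatigue L4 and R6 and low-fatigue
  L6 — the voxels where the emulated study localized its changes.  Effects
  can alternatively target the WM compartment in all voxels
  (`mode="wm_pool"`), which shifts the pure-WM projection endpoint by
  exactly the effect factor.
* One global seed fans out to per-subject substreams
  (`SeedSequence.spawn`), so identical (config, seed) pairs are
  byte-identical and subsetting subjects does not perturb the others.

Lesion images are synthesized as Gaussian background (100 ± 10, truncated
below threshold) plus a compact supra-threshold blob whose voxel count is
the target volume; the measurement inverts this by counting voxels at or
above the threshold (default background mean + 3 SD = 130) times the voxel
volume.  Real lesion masks can be measured through the NIfTI entry point,
taking voxel volumes from the header.

## What the synthetic data do not show

The generator emulates the *statistical structure* the analysis assumes —
composition gradients, mixture amplitudes, CRLB-linked noise, group effects
— not the physics of acquisition: no k-space, B0 inhomogeneity, baseline,
lipid/macromolecule contamination, phase or frequency drift, and no
segmentation errors (tissue fractions are exact up to sampling).  Passing
tests therefore establish that the pipeline recovers what its own model
family generates at realistic noise, not that it is robust to artifacts of
real scanner data.  Subject-level voxel tables from a real study can enter
the pipeline directly through the tidy CSV schema.

## Numerical choices

* CSVs carry 17-significant-digit floats and are parsed with round-trip
  precision, so a pipeline restart from any intermediate artifact is
  byte-identical to the uninterrupted run.
* The rational fit uses `xtol = ftol = 1e-14` and bounds γ ∈ (−0.95, 20);
  at zero residual the parameter covariance uses a pseudo-inverse (the
  Jacobian can be flat along reparameterization directions).
* Degenerate inputs: voxels with GM + WM = 0 and pure-CSF voxels are
  errors; missing ratios propagate as NaN and are dropped per-case; a
  bootstrap resample that fails to fit is recorded as missing rather than
  aborting the contrast.
* Analysis problem sizes: the multi-cohort checks run 100–200 simulated
  cohorts for effect recovery, false-positive rate and endpoint
  calibration, and 500 Monte-Carlo noise realizations per SNR for CRLB
  calibration — sizes at which the binomial/Monte-Carlo error is well below
  the tolerances being checked.

## Known limitations

* No absolute quantification (institutional units or water referencing) and
  no per-metabolite relaxation correction of fitted amplitudes; all claims
  are about ratios.
* The ANCOVA treats voxels independently (no mixed-effects modelling across
  the grid), matching the per-voxel reporting convention it emulates.
* The pure-tissue endpoints are extrapolations beyond the observed
  composition range (max fWM ≈ 0.9); their validity rests on the mixture
  model holding to the boundary.
* EDSS is compared nonparametrically but not modelled ordinally; depression
  screening is out of scope.
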