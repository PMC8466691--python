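# Methods

`myodti` implements two strategies for quantifying water diffusion in
skeletal muscle from diffusion-weighted MRI, together with the statistical
battery used to compare raters and methods, and a synthetic phantom that
supplies ground truth for validation.

## Signal model and tensor estimation

Per voxel the diffusion-weighted signal follows the single-tensor model

    S_i = S0 · exp(−b_i · g_iᵀ D g_i),

with b-values in s/mm² and the symmetric tensor D carried in units of
10⁻³ mm²/s (the unit the field's tables use; the conversion lives in the
design matrix). Estimation proceeds in three stages:

1. **Log-linear initialization** — ordinary least squares on
   ln S against the 7-parameter design (ln S0 and the six tensor elements).
2. **Weighted least squares** — iteratively reweighted with weights equal
   to the squared predicted signal, which undoes the heteroscedasticity the
   log transform introduces. Iteration stops at a relative parameter change
   below 1e-6 or after 20 iterations.
3. **Robust variant** — the IRLS loop is additionally down-weighted by a
   Geman–McClure function of the studentized log residual (robust scale =
   1.4826 · MAD, floored at 1e-10 to survive exactly-zero residual sets);
   measurements with |residual| > κ · scale (κ = 6) are flagged as outliers
   and a final plain WLS refit excludes them. If exclusion would leave
   fewer than 7 measurements or no b = 0 image, the non-robust fit is
   returned and the voxel flagged. These internals follow the published
   defaults of the robust outlier-rejection family of tensor estimators.

Numerical safeguards: non-positive signals are clamped to machine epsilon
for the log transform and the voxel flagged; the adaptive weights are
normalized per voxel before exponentiation so extreme initializations
cannot overflow; a design matrix with condition number above 1e8 (a
degenerate gradient scheme) is rejected outright.

Scalar maps come from a per-voxel eigen decomposition with eigenvalues
sorted descending: MD = (λ₁+λ₂+λ₃)/3, RD = (λ₂+λ₃)/2,
FA = √(3/2)·√(Σ(λᵢ−MD)²/Σλᵢ²) with FA ≡ 0 for an all-zero tensor. Negative
eigenvalues are **kept but flagged** rather than clamped: silent clamping
biases muscle means, so flagged voxels are excluded from MSB averaging and
their exclusion count reported. SNR is the mean b = 0 signal divided by the
local noise sigma; sigma = 0 voxels are masked, never infinite.

## Manual-segmentation-based analysis (MSB)

Muscle masks are smoothed by per-label binary closing (removes speckle
without shifting the boundary on average; closing may only claim background
so labels never invade each other), eroded by one voxel (default) with a
6-connected structuring element to shed partial-volume rims, then resampled
to the diffusion grid by nearest-neighbour lookup of each target voxel
centre through both affines. The per-muscle metric is the unweighted
arithmetic mean over valid in-mask voxels — every voxel counts exactly
once. Whole-calf fat fraction is the unweighted mean of the per-muscle mean
fat fractions (muscles count equally regardless of size), computed on
un-eroded masks.

The smoothing kernel and erosion connectivity are not pinned down by
convention in this field; both are exposed (`connectivity` 6 or 26,
`smooth` on/off) with the defaults above. Erosion happens before
resampling, i.e. in the grid the masks were drawn on.

## Volume-based tractography (VBT)

Deterministic streamline tracking inside each *un-eroded* muscle mask:

* seeds at every in-mask voxel centre with FA in the tracking range
  (1 seed/voxel default; more adds uniform intra-voxel jitter),
* bidirectional fixed-step Euler integration along the principal
  eigenvector, sign-aligned to the incoming direction at each step,
* the direction and FA at an arbitrary point come from trilinear
  interpolation of the six tensor elements followed by eigen decomposition
  at the interpolated point (non-finite or out-of-grid voxels contribute a
  zero tensor, so the field fades to FA 0 at the edge and acts as a
  barrier),
* a streamline end stops on mask exit (nearest-voxel test), FA leaving
  [fa_min, fa_max], a per-step turn above max_angle, or the step budget.

Defaults: max angle 15°, step 1.5 mm, FA range 0.1–0.6 — the standard
muscle fiber-tracking stop criteria — plus minimum length 10 mm and 2000
steps. Seeding density, interpolation scheme, integrator, step budget and
minimum length are implementation choices (muscle tractography toolboxes
differ here); all are config knobs and are embedded in every report.

Tract-based sampling maps every streamline point to its **nearest voxel**
(deliberately not interpolated) and averages over all points of all
streamlines, so a voxel's weight is literally its tract-visitation count.
This is the methodological contrast with MSB's once-per-voxel averaging: in
homogeneous tissue the two coincide; where a low-quality rim exists,
tracking avoids it and the visitation-weighted means shift away from the
voxel-averaged ones.

Tract properties per muscle: Vol = un-eroded mask volume (cm³) — defined on
the mask, not the tract envelope, because the delineated volume is the
segmentation object; TD = streamline count / Vol (so TD depends on seeding
density and is comparable only within a fixed configuration); MTL = mean
arc length (mm); mean angle = mean over all segments of the angle to the
craniocaudal +z axis in [0°, 90°] — the reference axis is an assumption
(slice-stack direction) and is logged in the output.

## Reliability statistics

All statistics use sample standard deviations (n−1). CV = SD/mean.
Paired t is the classical test on differences with explicit handling of
degenerate variance (all-zero differences → t = 0, p = 1; constant nonzero
difference → the p → 0 limit). ICC comes from the two-way ANOVA mean
squares with raters as a fixed factor; the default is **absolute
agreement, single measures** — ICC(A,1) — because the scientific question
is whether two raters produce interchangeable values, not merely
proportional ones. The consistency variant ICC(C,1) is always reported
alongside, and the model choice is embedded in the output metadata; this
is the most consequential ambiguity in reproducing ICC values across
software packages. Cronbach's α treats the two raters as items. Bland–
Altman reports mean difference, SD of differences and limits of agreement
at mean ± 1.96 SD. Reports pool all (subject, muscle) pairs by default —
the convention for two-rater muscle studies — and support restriction to
the fatty-infiltrated stratum (mean rater FF > 0.10). CV can equally be
computed across pooled values or from printed summary statistics
(`cv_from_summary`).

Note the ordering ICC(A,1) ≤ ICC(C,1) is guaranteed only when the
between-rater mean square exceeds the residual mean square (i.e. when a
systematic rater offset exists); with MSC < MSE the absolute coefficient
can exceed the consistency one by a small amount. The property test
conditions on MSC ≥ MSE accordingly.

## The phantom

The generator emulates a lower-leg acquisition: 17 diffusion directions at
b = 400 s/mm² (golden-angle hemisphere spiral, design condition ≈ 13) plus
three b = 0 volumes, on a 64 × 64 × 40 grid of 3 × 3 × 6 mm³ voxels.
Seven muscle compartments are angular sectors of an annulus around a
central bone void, with unequal sector widths so muscle volumes span a
realistic range (mean ≈ 190 cm³ at the default geometry). Each muscle's
fiber field is its outward radial direction tilted from +z by a fixed
anatomically plausible pennation angle (8–22°; the soleus is bipennate,
flipping its in-plane component across the mid-plane).

Tissue defaults are healthy-calf values: λ₁ = 1.97 and RD = 1.39
(10⁻³ mm²/s), i.e. MD 1.58 and FA ≈ 0.21, drawn per muscle with SDs 0.12
and 0.10 so repeated seeds mimic between-subject spread. Fat is a second,
isotropic compartment (diffusivity 0.2 × 10⁻³ mm²/s, a literature-typical
value, configurable): S = S0[(1−FF)·muscle + FF·fat]. The healthy preset
draws FF in 0.02–0.05, the NMD preset in 0.03–0.78 (the range observed in
dystrophic calves). Noise is Rician — magnitude of two independent Gaussian
channels — with sigma set by the target b = 0 SNR (default 59); the true
sigma is emitted as the noise map. An optional low-FA rim (rim thickness in
voxels; RD raised to 1.85 with λ₁ unchanged, FA ≈ 0.04) emulates
partial-volume contamination at muscle borders and drives the MSB-vs-VBT
divergence experiments.

Two simulated raters perturb each muscle boundary independently: surface
voxels are dropped and adjacent background voxels added with probability
0.15 per unit jitter, then the largest connected component is kept so no
muscle splits. At the default jitter of 1 this yields inter-rater Dice
≈ 0.87–0.93 per muscle, the level reported for expert manual muscle
segmentation. A muscle erased entirely raises an error.

What the phantom does **not** model: realistic anatomy (compartments are
prisms, not muscles), susceptibility/eddy/motion artifacts, registration
error between anatomical and diffusion space (all grids share one space),
the multi-peak fat spectrum and fat suppression, intramuscular FF
gradients, and spatially varying noise. Consequently, passing tests show
that the *algorithms* are correct and stable under realistic noise and
rater variability — not that scanner data would yield the same absolute
agreement. Tract density in particular depends on seeding density and is
not comparable across implementations.

## Problem sizes and tolerances

The test suite exercises the pipeline on 32³- to 48³-scale grids (a few
thousand voxels per muscle) and the acceptance script on the full default
geometry with 3 simulated subjects; both finish in minutes on one CPU.
Noise-free oracle checks assert to 1e-9 (tensor round trips) and 1e-12
(statistics vs hand-computed ANOVA/formula oracles); Monte-Carlo checks at
SNR 59 use 2% (diffusivity recovery), 2° (pennation), and 5% (SNR
recovery) bands. Fixed seeds make every stochastic check reproducible;
the phantom is bit-identical for a given seed.

## Known limitations

* Gradient directions are interpreted in the image frame; no scanner-frame
  rotation or b-matrix correction (preprocessing is upstream).
* The robust fit flags whole measurements per voxel; it does not model
  spatially correlated artifacts.
* Tracking is single-tensor and deterministic; crossing or fanning fiber
  configurations are out of scope.
* The Rician noise floor is not corrected for; at SNR 59 its bias on MD is
  far below the 2% recovery band, but the bias grows at low SNR.
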