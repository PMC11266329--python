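# Methods

`petmrac` is a desk-scale replica of a clinical evaluation question: how do
errors in the attenuation map used for PET reconstruction — in particular
the missing bone of a four-class Dixon MRAC and the small residual bone
errors of a synthetic CT — propagate into SUV quantification, thresholded
tumour delineation and a formal equivalence verdict? Because real patient
data, vendor reconstruction and a trained synthetic-CT network are outside
the package, every input is synthetic and every claim the tests make is
about the *mechanism* (sign, ordering, invariances, closed forms), not
about reproducing patient-data magnitudes.

## Digital phantom cohort

One patient is a stacked-2D voxel volume (default 128×128×9 at 3 mm
isotropic) containing:

* a superelliptical torso (|x/a|^p + |y/b|^p ≤ 1, default a = 160 mm,
  b = 110 mm, p = 2.5) with a 9 mm subcutaneous fat rim;
* three in-plane circular bone surrogates running through all slices (two
  femoral heads, radius 22 mm, and a sacrum, 20 mm; mean 700 HU, spread
  50 HU);
* a spherical rectal air pocket (radius 10 mm);
* an FDG activity truth in SUV units: soft tissue and bone at the
  background SUV (1.0), fat at 0.6× background, air at 0; spherical hot
  lesions (primary: 20 mm diameter at SUV 8; nodal: 12 mm at SUV 6) with a
  hard plateau and a one-voxel (3 mm) linear falloff — the plateau profile
  makes the 40 % threshold well-conditioned and lesion volumes analytically
  checkable;
* a manual tumour volume per lesion: a sphere 6 mm beyond the plateau.

HU values per class are typical CT numbers (air −1000, fat −90, soft
tissue +40, bone 700) with Gaussian texture (sd 10 HU) inside the body.
The study did not report lesion sizes or uptake levels, so these defaults
are the package's own choices of a plausible ano-rectal scenario; they are
exposed in the config and never tuned per run.

The default cohort is 10 patients carrying 9 primary and 5 nodal lesions
(so exactly one patient has no primary). Between-patient variation is a
seeded ±10 % jitter on body axes, bone radii and lesion size/uptake — enough
to give the per-lesion percentage differences a non-degenerate variance so
that standard errors and the TOST test are exercised meaningfully.
Randomness derives from one master seed: patient *i* uses the two children
of `numpy.random.SeedSequence([master_seed, i])`, so any single patient is
reproducible independent of cohort size.

What the generator deliberately does **not** emulate: real pelvic anatomy
beyond class composition, MR signal formation (ZTE/Dixon images are never
synthesized, only their downstream attenuation products), registration
error between modalities (maps are intrinsically co-registered), and
respiratory/bowel motion. Passing tests therefore demonstrate correct
propagation of attenuation errors through reconstruction and analysis, not
clinical performance on patients.

## Attenuation maps

All three maps per patient are expressed as 511 keV linear attenuation
coefficients (cm⁻¹) and prepared onto the same external support:

* **CTAC** (gold standard): the phantom HU volume through a bilinear
  piecewise-linear calibration anchored at (−1000 HU, 0), (0 HU, 0.096)
  and (1000 HU, 0.130 cm⁻¹) — standard air/water anchors with a reduced
  bone slope. The vendor curve is proprietary, so these anchors are
  defaults, configurable.
* **sCTAC**: the same conversion applied to a synthetic-CT-like HU volume
  that differs from truth only by a bone HU bias (default −30 HU) and an
  optional morphological bone-boundary shift.
* **MRAC**: bulk LACs per Dixon class (air 0, fat 0.086, soft tissue
  0.096 cm⁻¹; no lung in a pelvic field of view) after collapsing bone and
  internal air into soft tissue. The class values are in the range of
  published four-class implementations; the study cites but does not print
  its own.

Preparation rules: voxels outside the reference body contour are zeroed;
voxels inside it with LAC below 0.02 cm⁻¹ count as missing tissue and are
set to water; internal air pockets are set to water. The 0.02 cm⁻¹ cut
separates air from fat unambiguously on the default curve. Preparation is
idempotent and gives all three maps an identical external support.

## Acquisition and reconstruction

A 2D parallel-beam model is applied slice by slice: 96 angles over 180°,
192 radial bins at 3 mm. Line integrals use a Joseph-style ray tracer
(bilinear interpolation at unit-pixel steps); the backprojector is the
exact algebraic transpose of that gather, so the EM pair is matched and
the noiseless fixed-point property holds to floating-point accuracy.

One acquisition per patient is simulated from the activity truth
attenuated by the **CTAC** map (the physical truth); candidate maps enter
only through the attenuation factors folded into the reconstruction system
model — same data, same geometry, same settings, different correction,
which is exactly the comparison of interest. Expected counts are
`count_scale · exp(−∫μ dl) · ∫activity dl` with Poisson noise under an
explicit seed; the default `count_scale = 50` yields on the order of 10⁶
expected counts per slice, visible but not dominant noise.

OSEM uses 4 iterations × 16 angle-interleaved subsets and a 5.0 mm FWHM
Gaussian post-filter (σ = FWHM/2.3548 per axis), the settings of the
clinical protocol being emulated. Numerical guards: ε = 10⁻¹⁰ in EM ratio
denominators; voxels with zero sensitivity are frozen at 0 rather than
raising; the image is initialised to 1 inside the sensitive region. The
activity truth is already in SUV units, so the SUV conversion divides the
count scale back out (weight and dose travel as validated metadata).
Scatter, randoms, normalisation, decay, PSF modelling and time of flight
are deliberately absent: they are orthogonal to attenuation-error
propagation, and their absence is the main reason absolute bias magnitudes
here differ from scanner values.

## Evaluation metrics

* **External contour**: CTAC SUV ≥ 0.05 (interpreting the clinical
  0.05 g ml⁻¹ threshold as SUV, the standard g/ml-equivalent), largest
  connected component; the same contour is reused for all three images.
* **Percentage difference maps**: 100·(candidate − CTAC)/CTAC per voxel
  inside the contour; voxels with CTAC = 0 are excluded from the division
  and counted rather than clamped.
* **Histogram**: 400 bins of 0.5 % across ±100 %; per patient, the
  percentage of in-contour voxels per bin; cohort mean ± SE per bin. Binned
  fractions plus excluded voxels conserve the in-contour count. A
  single-patient cohort flags its SE as undefined.
* **Bone ROI**: thresholding the CT HU volume at 200 HU and removing
  connected components under 50 voxels.
* **GTV**: voxels inside the manual volume with SUV ≥ 40 % of the maximum
  SUV inside that volume, no connectivity filtering (whether the clinical
  tool filtered is unstated; keeping all voxels is the simpler contract).
  A global rescale of an image leaves its GTV voxel-identical and scales
  SUVmax/SUVmean by exactly that factor.
* **DSC** and **distance to agreement**: DTA is implemented as symmetric
  surface distances — boundary voxels by 6-connected erosion difference,
  distances pooled over both directions, mean and maximum (symmetric
  Hausdorff) in mm. The clinical system's exact DTA definition is
  unpublished, so a directed variant is available and symmetric is the
  default. Note one geometric subtlety: for square masks the corner-to-
  corner distance of a one-voxel ring is √2 × spacing, not spacing.

## Equivalence statistics

The margin derivation treats attenuation correction as an independent
addition to the PET-CT uncertainty budget: Δ_total = √(Δ_base² + Δ_AC²).
With the literature PET-CT SUV repeatability of 12 % and an allowed total
growth of 0.5 %, the margin is √(12.5² − 12²) = 3.5 %.

Equivalence of per-lesion percentage differences (SUVmax and SUVmean, each
candidate map, each GTV kind — 8 comparisons) uses two one-sided paired
t tests with df = n − 1 and SE = sd(n−1 denominator)/√n; the reported p is
the larger of the two one-sided p-values, and equivalence is declared at
p ≤ α/(n_tests − 1) = 0.05/7 ≈ 0.007. The divisor n − 1 (not the plain
Bonferroni n) is kept deliberately because it is the correction this
analysis is defined with; the rounded 0.007 is for reporting, the exact
value decides. A degenerate SE of 0 (identical differences, e.g. a
zero-error synthetic CT) returns p = 0 if |mean| < margin and 1 otherwise,
with a warning.

## Problem sizes and verification

The default study — 10 patients × 3 reconstructions at 128² × 9 slices —
was chosen so a full run completes in a few minutes on one core while still
carrying 14 lesions through all 8 equivalence tests. The test suite checks
each stage against independent oracles: analytic sphere volumes, chord
lengths and exp(−μd) closed forms, a discrete Gaussian kernel, brute-force
voxel loops, hand-counted Dice/DTA cases, and statsmodels' paired TOST
(agreement to 10⁻⁸). The five headline TOST p-values recomputed from the
printed summary statistics (0.007, 0.03, 0.04, 0.95, 0.83) match at
printed precision; two other printed p-values (0.002 and 0.88) do not
round-trip from their own printed summaries — evidently computed from
unrounded data — and are documented rather than asserted.

## Known limitations

* Stacked-2D acquisition; no 3D ray crossing between slices (the
  post-filter does couple slices).
* Bias magnitudes (e.g. the bone-region MRAC underestimate) are larger
  than scanner values because the phantom's bone fraction and the absence
  of scatter/PSF/TOF differ from the clinical chain; only signs and
  orderings are claimed.
* Single calibration curve; no kVp dependence, no hardware (coil/couch)
  attenuation.
* No observer variability in the manual volumes; they are geometric
  spheres by construction.
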