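# Methods

`scatterscale` is a desk-scale laboratory for one question in quantitative
brain PET: what happens to scatter correction — and everything downstream of
it — when the transmission scan (the mu-map) and the emission scan are
misaligned because the patient moved between them, and how a *margin* on the
attenuation-correction-factor (ACF) sinogram protects the scatter scaling.
Every component runs on synthetic phantoms with known ground truth, so each
effect can be measured against an oracle rather than inferred statistically.

## Scanner model

A miniature cylindrical scanner is parameterised parallel-beam style:
projection bins are indexed by (segment, plane, angle, radial bin), where a
segment collects LORs of a fixed ring difference (segment 0 is direct,
in-plane) and a plane within segment *d* is an ordered ring pair. Defaults
are 8 rings, 96 angles, 128 radial bins at 1.525 mm pitch; the test and
experiment configurations scale this down further (4 rings, 48 angles, 96
radial bins at 1.22 mm — the pitch at which an 8-bin margin is the ~10 mm
margin of the clinical setting) so the full pipeline stays inside a
single-CPU time budget. All counts and pitches are configuration.

Forward projection samples each LOR at half the smallest voxel pitch with
trilinear interpolation; back projection applies the exact transpose
weights, so the pair passes a dot-product adjointness test at float64
round-off (the OSEM derivation assumes this). ACFs are `exp` of the mu line
integral; bins missing the object are exactly 1. Poisson noise is applied
to the scaled expectation with a seeded generator; identical seeds give
bitwise-identical data.

## Phantom and tracers

The head is a soft-tissue cylinder (mu = 0.0096/mm) spanning the axial FOV,
wrapped in a 4 mm skin shell, with two spherical grey-matter-like regions:
one central, one "lower brain" placed low in the FOV where the clinical
artefact lives. The phantom deliberately continues "beyond" the axial FOV:
when the mu-map is shifted axially to emulate motion, edge planes are filled
by nearest-neighbour extension, not vacuum — a head continues into a neck,
and vacuum fill would fabricate object-free planes that no *radial* margin
could ever exclude.

Three tracer profiles drive regional kinetics (rates are plausible
desk-scale choices, not clinical claims):

* **verapamil-like** — 1T, low brain uptake (V_T ~ 1), skin K1 three times
  brain K1: the hot rim at the patient contour that makes tail fitting
  fragile under mismatch;
* **raclopride-like** — reversible 2T with elevated k3/k4 in the central
  (striatum-like) region;
* **flumazenil-like** — 1T with high K1, cold rim.

The plasma input is a linear rise to a peak (30 s, 50 kBq/ml) followed by a
tri-exponential decay; whole blood is plasma times 0.8 (no metabolites).
Frame activity images are the frame-averaged compartment-model curves
painted onto the label map; trues are the attenuated forward projection.
Both are linear in activity, so per-label building blocks are combined per
frame.

## Single scatter simulation

For a detector pair (A, B) and scatter point S (a coarse grid, default 8 mm,
restricted to mu > 0.002/mm), the single-scatter contribution sums, over
both leg assignments, the emission integral along the unscattered leg, 511
keV attenuation on that leg, attenuation at the Compton-shifted energy
E' = 511/(2 − cos θ) keV on the scattered leg, the Klein–Nishina
differential cross-section at θ, inverse-square distances, and an energy
acceptance factor. Numerical choices:

* attenuation at E' scales mu by the total Klein–Nishina cross-section
  ratio σ(E')/σ(511) — Compton dominates in soft tissue at these energies;
* the energy window is a step at 400 keV smoothed by a Gaussian of constant
  absolute FWHM 0.17 x 511 keV (scanner-typical values; the √E scaling of
  scintillator resolution is a refinement the desk scale does not need).
  The end-to-end *experiment* configuration lowers the step to 250 keV: the
  desk detector ring is several times smaller than a brain scanner's, so
  radial offsets in the margin-fit zone correspond to scatter angles whose
  400 keV acceptance is essentially zero — the tail would end in a cliff
  exactly where margins 8–14 fit, and a few-mm mu-map shift displaces the
  model's cliff against the measured one, making the fitted scale
  meaningless. Scaling the window with the geometry keeps the fit zone
  physical; the physics-level checks (scale recovery against a true-
  configuration model) run at the native 400 keV window, as does the 2D/3D
  mode comparison, which involves no mismatch;
* the estimate is computed on a coarse (angle, radial) grid (defaults 12
  angles x 17 radial knots) and bilinearly interpolated — single scatter is
  spatially smooth, and halving the scatter grid changes the estimate by
  < 3 % RMS (tested).

**2D vs 3D.** `sss3d` evaluates every oblique segment's true geometry;
`sss2d` evaluates direct planes only and fills oblique bins by
axial-midpoint interpolation between direct planes. For an axially uniform
object the two collapse (≤ 5 % RMS); an axial activity gradient separates
them — this is the experiment scaffold for the 2D/3D comparison.

**Scatter ground truth and non-circularity.** The acquisition simulator
generates its scatter component with the same SSS operator evaluated on the
true, unshifted configuration, then broadens it with a Gaussian along the
*angle* axis (sigma 2 bins). The broadening decorrelates the truth from the
estimator's exact kernel; it acts along angle only because the radial tail
has a steep, energy-window-driven shoulder on which any radial smoothing is
multiplicatively violent (tens of percent exactly where the margin fit
samples), whereas angular profiles are gentle everywhere. The oracle scale
s\* is defined as the least-squares scale of the model to the true scatter
over *all* bins — what a fit would return with the full noiseless scatter
signal in hand.

## Tail fitting and the ACF-margin

The object band is {ACF > 1.03}; the tail is its complement after dilating
the band radially by the margin (radial only: a transverse mismatch
displaces the object's radial silhouette; this mirrors the widened band of
the clinical implementation). The scale is s = Σ y·m / Σ m² over tail bins,
clamped at zero — per (segment, plane) with nearest-fitted-plane fill-in for
planes with fewer than 20 tail bins, or pooled over all planes. The margin
is used **only** for this fit, never for attenuation correction.

The mechanism under study falls out directly: with a 5 mm radial mu-map
shift and the rim-hot phantom, true emission counts sit in bins the shifted
ACF calls object-free, and the margin-0 fit overestimates s\* by a factor
of ~2; by an 8-bin margin the fit is back within a few percent. Aligned
acquisitions stay within 5 % at every margin from 0 to 14.

## Reconstruction

Ordinary-Poisson OSEM with the model ybar = (1/ACF)·P(x) + s; the scaled
scatter estimate enters as an additive term in the prompt domain (it is fit
against prompts, so this placement is self-consistent; the alternative
pre-ACF placement would require scaling the tails by ACF ≈ 1 there —
immaterial at this scale but documented as the choice). Updates run over
angle subsets in bit-reversed order from a uniform cylinder; sensitivities
are per-subset backprojections of 1/ACF; zero-sensitivity voxels are masked
and logged. With 1 subset and no additive term the update conserves total
modelled counts exactly (the classic MLEM identity; with an additive term
the conserved quantity is different, which is why the conservation check
runs at zero scatter). An optional isotropic Gaussian PSF in projection
space stands in for resolution modelling; off by default.

The dynamic pipeline per frame: a short no-scatter OSEM pass, an SSS
estimate from it (using the delivered, i.e. possibly shifted, mu-map), the
margin-masked tail fit, and the final OSEM. The preliminary image still
contains the uncorrected scatter haze, which biases the model *shape*; a
second outer loop (re-estimating the model from a scatter-corrected
reconstruction) is available but off by default. The residual effect is a
common multiplicative bias of reconstructed activity (roughly −5 to −15 %
against truth at a 35 % scatter fraction at desk scale); the study's
endpoints are ratios across margins/modes of the *same* acquisition, from
which this common bias cancels. Frames are calibrated from count space back
to kBq/ml with the known simulation count scale.

## Kinetics

1T and reversible 2T plasma-input models with a blood volume fraction:
C = (1 − Vb)·C_tissue + Vb·C_b; V_T = K1/k2 (1T) or K1/k2·(1 + k3/k4) (2T),
held as an identity of every fit. Convolutions use recursive
exponential-kernel trapezoid quadrature on the input's 1 s grid (exact
recursion per step, `lfilter`-implemented; no FFT edge artefacts), then
frame averaging. Fitting is weighted NLLS (weights = frame duration by
default; the clinical choice is not stated anywhere authoritative), bounds
K1, k2, k3, k4 in (0, 2], Vb in [0, 0.2], three fixed starts, best-of; fits
report an honest convergence flag instead of raising.

## Motion QC

Displacement is √(Δx² + Δy² + Δz²). Registration is translation-only:
normalised FFT cross-correlation evaluates every voxel-step translation
(this *is* the grid search, at voxel step), a search window restricts the
argmax, and per-axis parabolic interpolation refines below the step.
Sub-voxel-pitch `step_mm` requests are therefore not honoured below one
voxel. The QC registers each frame against the duration-weighted sum of
frames starting in the first 60 s (motion inside that window is
undetectable by construction); frames under 10³ counts are skipped with a
warning.

## Experiments

"Subjects" are seeds: ±10 % jitter on kinetic parameters and a random
mismatch direction (configurable to transverse-only or pure-radial for
controlled checks). The margin sweep reports, per subject x margin x VOI,
the fitted-to-oracle scale ratio, summed-image (frame 5 to last) VOI means
and V_T with ratios to the 8-bin-margin reference and to kinetic truth, and
a plateau margin (smallest margin beyond which the largest V_T change is
under 2 %). The 2D/3D comparison fixes the margin at 8 bins. Experiment
tail fits are pooled rather than per-plane: desk-scale planes hold too few
tail counts for stable per-plane scales, and the flagged-plane fill-in would
dominate. Group significance tests are replaced by truth-referenced bias —
simulation knows the answer, so inferential statistics would add nothing.

## What a green test establishes — and what it does not

The generator emulates: tracer-dependent regional kinetics with a hot rim,
Poisson counting statistics, attenuation from a misaligned mu-map, and a
smooth single-scatter background of stated fraction. It does **not**
emulate: multiple or out-of-FOV scatter, randoms, dead time, decay,
normalisation, detector physics, rotational motion, intra-frame motion, or
metabolite kinetics. Green direction checks therefore establish that the
margin mechanism and the 2D/3D oblique effect behave as described *within
this stated world*; clinical magnitudes (the 43 %/24 %/7 %/4 % figures of
patient studies) are not reproducible at desk scale and are not claimed.

## Known limitations

* Single scatter only; the estimator's own model is used to generate the
  (broadened) truth, so absolute scatter realism is out of scope.
* One scatter outer loop leaves a common absolute activity bias; endpoints
  are ratio-based.
* The 2D-SSS midpoint fill-in is exact for axially uniform objects, so 2D/3D
  differences only appear with axial structure — by design.
* Registration is translation-only; rotations are out of scope.
* Per-plane tail fitting is implemented and tested, but count-starved at
  desk scale; experiments pool planes.
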