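# Methods

## Pipeline

The pipeline mirrors a proximal-sensing greenhouse workflow: each scene is
a pallet of plants with a white reflectance standard in the frame, imaged
simultaneously by an RGB camera and a 400–1000 nm hyperspectral camera
(204 bands, ~3 nm sampling), with dark-adapted F0/Fm fluorescence maps for
the same pixels. Processing steps:

1. **White normalization.** Per-channel means over the white-standard patch
   divide the raw channels. All six RGB indices are ratios, so they are
   invariant to any gray rescaling; normalization matters only when channel
   gains differ.
2. **Segmentation.** RGB score windows (strict inequalities, exactly the
   printed thresholds 115.33–139.3 for pea and 36.39–140 for wheat, applied
   to raw 8-bit channels) or strict NDVI thresholds (0.5 pea, 0.4 wheat).
   Both families are exposed; window bounds are arguments, because the
   wheat numerator `0.1·G − R` is positive only when `G > 10·R`, which
   constrains which canopies the printed window can accept.
3. **ROI averaging.** Ten rectangles per image (a deterministic 2 × 5 grid
   over the plant region by default; a CSV of labelled rectangles
   overrides). Per-pixel index values are averaged over plant pixels inside
   each rectangle; an empty ROI yields a missing value, never zero.
4. **Statistics.** Cell means per (species, treatment, day) feed pooled
   Student's t-tests (control vs. treated, per day), Pearson correlations
   with the t-distribution critical |R| (0.576 at n = 12, α = 0.05), and
   per-species OLS calibrations of Fv/Fm, NDVI and PRI on each RGB index.
   Missing cells are dropped pairwise; no multiple-testing correction is
   applied. Correlations are evaluated on control + drought cells (n = 12)
   and control + NaCl cells (n = 24); calibrations pool all five arms
   (n = 30).

Mask routing in the default `split` mode: RGB-window mask for RGB indices,
NDVI mask for NDVI/PRI, and the ground-truth mask for Fv/Fm — the latter
emulates a handheld fluorometer measured directly on plants rather than a
reflectance-gated reading. `rgb`, `ndvi` and `truth` modes route one mask
everywhere.

## Synthetic scene generator

No imagery is deposited with the study design this package emulates, so
the generator is first-class, tested code rather than a fixture.

**Leaf optics.** Reflectance is a smooth baseline (visible level rising
through a sigmoidal red edge at ~715 nm to an NIR plateau of 0.5) minus
generalized-Gaussian absorption wells scaled by relative pigment contents
in [0, 1]: chlorophyll wells in the red (680 nm for pea; a broad flat-top
well at 650 nm for wheat), a shallow chlorophyll well at 600 nm, a blue
chlorophyll well at 430 nm, and a carotenoid well at 470 nm. Two
refinements matter:

* *Beer–Lambert saturation.* Each well realizes a fraction
  `1 − (1 − p)^γ` of its depth at pigment content `p`. The deep wheat red
  well uses γ = 6: optically thick red absorption stays dark until
  chlorophyll is nearly gone, while the shallow green-shoulder well
  responds linearly. This is what lets the printed wheat mask window
  (which requires very low red) keep accepting moderately stressed wheat
  pixels that are already shifting in green.
* *The 600 nm well* makes pigment loss raise reflectance at 570 nm faster
  than at 531 nm, so PRI declines as pigments degrade — the pigment-driven
  part of PRI behaviour. Xanthophyll-cycle dynamics are deliberately not
  modelled.

Default well depths were chosen once so that healthy canopies land
mid-window for both species masks, healthy NDVI is ~0.75 (pea; in the
0.6–0.9 range typical of dense green canopies), and the soil background
(a stylized flat, slightly rising damp-substrate spectrum) falls outside
every mask. This is a three-well-family absorption sketch, not radiative
transfer: no PROSPECT/SAIL, no canopy geometry, no BRDF.

**Stress trajectories.** Treatment severities are ordered
control (0) < NaCl 100 mM (0.5) < 200 mM (0.7) < 400 mM (0.95) ≤ drought
(1.0). Pigments decline linearly from day 1 to day 12 (maximum relative
chlorophyll loss 0.7 at full severity); carotenoids decay at half the
chlorophyll rate under drought and at the same rate under salinity. A
latent vitality state declines from day 5, and Fv/Fm = 0.8 × vitality, so
control canopies sit at ~0.8 and day-12 drought reaches ~0.2 (pea) or
~0.1 (wheat, whose drought decline is deeper). Measured RGB-index changes
therefore emerge around day 3 and Fv/Fm changes around day 8, reproducing
the earlier sensitivity of RGB indices.

**Within-canopy heterogeneity.** Each plant pixel realizes a fraction
`u ~ Uniform(0, 1)` of its arm's pigment loss, plus small Gaussian jitter
(σ = 0.004) on all state variables. Real stressed canopies retain greener
leaves; without this tail, threshold masks would empty every ROI late in
severe arms. Vitality is spatially uniform up to jitter so the scene-mean
Fv/Fm tracks the arm's trajectory exactly.

**Sensor model.** RGB channels are boxcar means of reflectance over
600–700 / 500–600 / 400–500 nm scaled to 0–255 (half-up rounding); the
camera's true spectral responses are unknown, and a flat spectrum of 1.0
maps to (255, 255, 255) by construction. Pixel intensity noise is
lognormal multiplicative (σ = 0.05) applied to the whole spectrum of each
pixel — spectrally flat, so ratio-based scores are unaffected — and the
white patch is rendered noise-free, as a calibration standard should be.
Scenes are 60 × 120 px by default (white patch top-right, 2 × 5 ROI grid
below, one plant blob per ROI covering ~35 % of it), small enough that the
full 60-scene design renders in seconds while every downstream statistic
retains its design sample sizes.

**Seeding.** One integer seed fans out through `SeedSequence` spawn keys
indexed by (species, treatment, day), so draws never depend on the order
in which bundles are generated; identical (config, seed) gives
bit-identical scenes.

## Numerical choices

* Undefined denominators (zero channel sum; `R' = 0` or `B' = 0` for VEG;
  `G' + R' − B' = 0` for VARI; `Fm = 0` or `F0 > Fm`) yield NaN, which ROI
  averaging excludes and downstream statistics drop pairwise.
* The VEG exponent is stored exactly as the printed constant 0.667, not
  2/3.
* Narrow bands are resolved by nearest-wavelength match with a 5 nm
  tolerance (the ~3 nm grid guarantees a hit); ties take the lower index.
* Mask windows and NDVI thresholds are strict on both ends.
* Constant inputs make Pearson R and OLS undefined; both return missing
  (guarded by exact max = min tests, not floating-point variance).
* RGB indices are computed per pixel and then averaged (the averaging of
  index values, not channels); channel-first averaging is available only
  as a sensitivity switch via the library by averaging channels manually.

## What the synthetic tests do and do not show

Passing tests demonstrate that the implementation is internally
consistent: segmentation recovers ≥ 90 % of true plant pixels on healthy
scenes, indices match scalar reference arithmetic, correlations reproduce
the structural pattern (g and ExG rows identical; strong positive
g/ExG/VARI correlations with all three targets, negative for r; the weakest
calibration being wheat Fv/Fm), and OLS recovers known affine calibrations
at realistic noise. They do not validate the pipeline against real
canopies: the generator has no specular highlights, shadows, soil
moisture variation, overlapping-leaf geometry or illumination drift, and
its decay rates are calibrated only to qualitative dynamics. Calibration
slopes fitted on synthetic scenes are therefore not transferable to real
imagery; species-specific re-calibration on measured data is required.

## Known limitations

* The printed wheat RGB-mask window accepts only very-low-red pixels; on
  synthetic wheat this truncates masked means toward healthier pixels and
  weakens wheat NDVI/Fv/Fm calibrations (R² ~0.5–0.67) relative to pea.
  The window is kept exactly as printed; alternative windows can be passed
  explicitly.
* Under severe late-stage stress the NDVI thresholds legitimately reject
  most degraded pixels; heterogeneity keeps ROIs populated, but masked
  means are then conditional on surviving pixels.
* Wheat `b` dynamics under salinity are dominated by the red-band release
  and do not reproduce the reported blue increase; pea `b` does increase
  under salinity.
* The t-test is the pooled-variance Student form by default (a Welch
  variant is provided); zero-variance degenerate samples are flagged
  rather than tested.
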