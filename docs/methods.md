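# Methods

## The mapping model

Energy-filtered TEM selects electrons whose energy loss falls inside a
slit-defined window. Under a core-loss edge the background intensity
decays with energy loss `E` approximately as a power law,

    I(E) = A · E^(−r),

with `A` and `r` varying from pixel to pixel. Two pre-edge windows with
equal width `w` and centres `E_PP < E_P` (both below the edge onset)
determine the exponent per pixel,

    r = (log Iw_P − log Iw_PP) / log(E_PP / E_P),

the amplitude `A = Iw · E^r` (computable from either window — the two
values must agree, which the package uses as a consistency check), and
the background constant in the core window,

    k = (E_C / E_P)^(−r),  k ∈ (0, 1] for r ≥ 0.

The elemental map is the residual `map = Image_C − k · Image_P`. The
two-window baseline `Image_C − Image_P` is also provided; on a decaying
background it leaves a systematically negative residual of magnitude
`A (E_P^−r − E_C^−r) w`, which is why the three-window estimate is
preferred.

Window-integrated intensities use the centre-energy approximation
(spectral value at the window centre times the width). With that
convention the three-window algebra is *exact* on a pure power law: the
pipeline's end-to-end test exploits this, requiring machine-precision
cancellation on noise-free synthetic backgrounds. An exact-integration
variant of the window intensity exists only as a test oracle.

**Exposure normalisation.** The acquisition protocol gives the pre and
core windows several times the prepre exposure (e.g. 4 s / 20 s / 20 s).
Raw counts are therefore not on a common intensity scale; the exponent
and amplitude computations normalise to counts per second whenever the
inputs carry exposure metadata. The final subtraction rescales the
pre-edge image by the core/pre exposure ratio (unity in the standard
protocol, where those two exposures are equal).

**Masking, not clamping.** Pixels whose raw counts are at or below a
floor (default 1 count) are marked invalid before the logarithm; at low
dose a clamped logarithm fabricates exponents. Exponents outside
[−10, 10] (hot or dead pixels) also flip the validity bit. Negative map
values are retained in stored output; clipping is a display concern.

**Low-dose behaviour of the per-pixel exponent.** `E[ln N] =
ln λ − 1/(2λ) + O(λ⁻²)` for Poisson counts, so the per-pixel log-ratio
exponent is biased when window counts per pixel are small (tens of
counts at the 25k-magnification dose, single digits at 4k). An optional
boxcar pre-smoothing of the two pre-edge images (off by default, which
matches direct per-pixel computation) reduces this bias roughly in
proportion to the smoothing area. For *scene-wide* exponent estimates
the package pools the window intensities over the ROI before the
log-ratio — the same operation the spectral mode performs — which makes
the bias negligible at any realistic dose; the acceptance script
estimates exponents this way.

## Ice thickness and dose accounting

Thickness uses the log-ratio method,

    t = Λ · ln(I_unfiltered / I_zero-loss),

with the inelastic mean free path `Λ = 400 nm` by default (appropriate
for 300 kV electrons in vitreous ice; configurable). Pixels where the
ratio is below 1 (filtering cannot add electrons) or the zero-loss
intensity is non-positive are flagged invalid.

Dose records follow the acquisition protocol: the total exposure of one
imaging acquisition is prepre + pre + core (the pre and core windows
share an exposure time, so it equals prepre + 2·pre); the short
zero-loss exposure is tracked separately. Total dose = dose rate ×
total exposure, rounded **half away from zero** at the precision at
which the protocol prints it (456.5 → 457; banker's rounding would give
456). Spectral sessions sum the core-loss exposures of all elements
measured back-to-back on the same ROI. Multi-element imaging budgets
are sums of per-element records.

The signal-to-background ratio is the mean map (or raw-image) intensity
over a foreground mask divided by the mean over a disjoint background
mask (medians behind a flag); the statistic is invariant under global
intensity scaling. The spectral box-sum uses a 101-sample sliding
window by default, raw sums with truncated, flagged edge samples.

## Drift correction

Registration is upsampled phase cross-correlation, translations only
(drift at a cooled stage is small; rotation/scale are out of scope).
Shifts are reported as `(dy, dx)` displacement of the image content
relative to the template. Dose-fractionated frames are registered to
the *first* frame of the stack and summed; per-frame counts are in the
single digits at protocol doses, so a Gaussian low-pass (σ = 2 px by
default) is applied to both images before correlating — the filter
commutes with translation, so the measured shift is unbiased, and it
never touches the summed counts. Frames that fail to register fall back
to the previous frame's shift and are logged.

Between energy windows, images are registered to the zero-loss template
on Sobel gradient magnitudes of low-pass-filtered images: gradient
magnitude is invariant to the contrast inversion between zero-loss
(particles dark) and energy-filtered (particles bright) images.
Correlation ties break toward the smaller shift. Integer shifts are
exact translations; fractional shifts use Fourier-domain shifting.
Shifted-in border pixels are zero-filled and excluded through the
validity mask, which propagates into the mapping stage. A measured
shift beyond `max_shift` (default a quarter of the image extent) raises,
naming the window: drift of that size means registration failed.

## The synthetic scene simulator

The simulator is phenomenological — enough physics to exercise every
pipeline stage with known ground truth, no more:

* **Background.** Per pixel, `A = a · t_total` with `t_total` the local
  thickness (ice + carbon film + particle chord, nm) and
  `a = 40 (beam fraction)·eV^r/nm` by default; `r = 3.0` and spatially
  constant unless overridden. The default `a` puts ≈3 % of the beam
  into a 20 eV window at 117 eV over 60 nm of ice — single-digit to
  tens of counts per pixel at protocol doses, which is the regime the
  real method operates in. A single global power law cannot describe
  the background at both 100 eV and 350–530 eV, so scenes built for
  high-energy edges (Ca, O) should scale `a` up to keep window counts
  realistic there; the tests do this explicitly.
* **Edges.** Each element's core-loss edge multiplies the background by
  `(1 + J · coverage)` at every energy **at or above its onset** — a
  flat multiplicative step. A step present in all three windows cancels
  exactly in the three-window algebra, so only edges whose onset falls
  between the pre and core window centres contribute to a map; this is
  precisely what the window geometry is designed for, and it makes
  multi-element scenes consistent without special cases. The
  ground-truth map (`true_jump_image`) is exact provided no onset falls
  between the prepre and pre centres (a mis-chosen triplet).
* **Jump ratios** are model assumptions, not measured values: the
  protocol does not print edge-jump magnitudes. They are calibrated so
  that a 10 nm silica particle in ~60 nm of ice sits at the margin of
  detectability at the published 502 e⁻/Å² budget (J_Si = 0.6; full
  dose detects essentially all particles, a tenth of the dose loses a
  substantial fraction), with other elements set relative to Si
  following qualitative edge strengths (Ca 0.8 > O 0.7 > Si 0.6 >
  C 0.5 > P 0.4; the Ca white lines are sharp and strong, the P edge
  weak and plasmon-embedded).
* **Particles** are spheres: the thickness contribution at each pixel
  is the chord `2√(R² − d²)`; the per-element coverage profile is the
  particle's `coverage` parameter (fraction of beam path occupied at
  the centre) times the normalised chord profile. Overlapping particles
  of one element take the pointwise maximum coverage.
* **Zero-loss and unfiltered images.** The zero-loss image is the
  unfiltered image times `exp(−t_total/Λ)`, so the log-ratio thickness
  estimate closes exactly by construction. Dense material (film and
  particles) additionally attenuates *both* images by
  `exp(−t_dense/Λ_elastic)` with `Λ_elastic = 100 nm` by default — an
  objective-aperture loss term that gives the zero-loss image realistic
  particle contrast (a 10 nm silica particle dips ~12 % instead of the
  ~2.5 % pure inelastic contrast) without perturbing the thickness
  ratio, because it cancels in the quotient.
* **Noise.** Counts are Poisson with mean = expected beam fraction ×
  dose rate (e⁻/Å²/s) × exposure (s) × pixel area (Å²); detector gain
  is 1 count per electron, with no MTF/DQE, radiation damage, or
  multiple-scattering model. Zero dose yields all-zero images. All
  randomness derives from one explicit seed with deterministic
  per-image substreams, so acquisitions are bit-reproducible.
* **Spectra.** 1-D spectra are a Gaussian zero-loss peak, a Gaussian
  plasmon bump (23 eV), a power-law tail switched on smoothly above the
  plasmon region, and a sigmoidal step (width ≈ 2 eV) at each edge
  onset, Poisson-sampled when seeded.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: phase contrast and defocus
effects, beam-induced local motion (drift is a rigid translation),
plural/multiple scattering (real low-loss backgrounds under ~100 eV
edges are plasmon-dominated, not a clean power law), detector response,
and chemical fine structure on the edges. The pipeline's *algebra* and
its noise behaviour are exercised faithfully; absolute detectability
claims transfer to real data only to the extent the assumed jump ratios
do.

## Particle analysis

The size-distribution pipeline: block binning (default 4×4, block-sum —
counts are additive and summing preserves Poisson statistics; mean
binning exists for display), median filter (disk radius 2), inversion
when particles are dark (zero-loss contrast), rolling-ball background
subtraction (default radius 50 binned px; the radius must exceed the
largest particle radius, or particle interiors are treated as
background), 8-bit min–max conversion, binarization (Otsu by default;
isodata, triangle, or a fixed threshold available — the protocol names
the operation but not the threshold), small-object removal, and
watershed on the Euclidean distance transform. Watershed seeds are
local maxima of the (lightly smoothed, to break plateau ties) distance
transform, merged when closer than `min_separation`; watershed can be
disabled. Axis lengths come from the second-moment ellipse, reported in
nm via the binned pixel size; circularity is `4π·area/perimeter²`
(slightly above 1 is possible on small rasterized disks; the tests
tolerate up to 1.05).

The small-particle (10 nm) procedure bins 8×8, Gaussian-blurs (σ = 1.0
binned px for the zero-loss channel, 2.0 for the elemental map),
inverts the zero-loss channel, converts both to 8 bit, binarizes, and
superposes the masks. Sigmas are interpreted in binned pixels. A truth
particle counts as *recovered* only when at least half its footprint
lies inside the overlap mask: at very low dose the binarization
degenerates into a dense noise mask that merely touches everything, and
intersection alone would count those as detections.

## Numerical and design choices

* Coordinate convention: row-major arrays, origin top-left, pixel
  centres at integer coordinates, shifts `(dy, dx)`.
* Output images are 32-bit float (aligned sums of subpixel-shifted
  frames are non-integer). Metadata (window, exposure, dose rate, pixel
  size) travels in a JSON sidecar; an image without one loads with
  unknown metadata and a logged warning.
* MRC support is a deliberately minimal MRC2014 implementation (modes
  0/1/2/6, little-endian, no extended header on write) sufficient for
  single images and frame stacks; TIFF (single and multipage) is the
  primary format.
* Problem sizes in tests and the acceptance script (16×16 flat scenes
  for pooled-exponent statistics, 768² px detection fields with 16
  particles, 100-seed ensembles) were chosen as the smallest sizes at
  which each statistical check has meaningful power.

## Known limitations

* The forward model's edge step is flat above onset; real edges decay
  and carry fine structure, so window placement sensitivity is milder
  here than in practice.
* Per-pixel exponent maps are biased at single-digit counts (see
  above); the package surfaces smoothing and pooling as remedies but
  does not implement a debiased estimator.
* No plural-scattering deconvolution: thick-specimen spectra where the
  plasmon dominates the pre-edge region violate the power-law
  assumption in ways the simulator does not reproduce.
* Registration is translation-only and global per image.
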