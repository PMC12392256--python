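# cryoeels

Elemental mapping of light elements (Si, C, O, P, Ca) in frozen-hydrated
specimens from energy-filtered cryo-TEM image series — the three-window
background-subtraction method, with the drift correction, dose and
ice-thickness accounting, and particle-analysis procedures that make it
work at cryo-compatible electron doses.

**Who it is for.** Electron microscopists and image-analysis people who
acquire EELS window images (prepre-edge, pre-edge, core-loss) of
nanoparticles or biomaterials in vitreous ice and want a tested,
scriptable implementation of the mapping computation — plus a synthetic
scene simulator so every stage can be validated end-to-end without real
micrographs.

## The method

The energy-loss background under a core-loss edge decays as a power law
`I(E) = A·E^(−r)`. Two pre-edge windows of equal width determine, per
pixel,

```
r = (log Iw_P − log Iw_PP) / log(E_PP / E_P)
A = Iw_PP · E_PP^r = Iw_P · E_P^r
k = (E_C / E_P)^(−r)
map = Image_C − k · Image_P
```

where `E_PP, E_P, E_C` are the window centres. The residual `map` is the
elemental signal. Because dose must stay low over ice, the pipeline
around this algebra matters as much as the algebra: dose-fractionated
frames are registered and summed (`align_and_sum`), window images are
registered to a zero-loss template (`align_window_series`), ice
thickness comes from `t = Λ·ln(I_unfiltered / I_zero-loss)` with
`Λ ≈ 400 nm` at 300 kV, and every acquisition's electron budget is
tracked (`dose_budget`). Particle size distributions and the
small-particle enhance-and-superpose colocalization procedure are in
`cryoeels.particles`.

The built-in simulator (`cryoeels.synthetic`) generates zero-loss,
unfiltered and window-triplet images of spherical particles in ice with
power-law backgrounds, multiplicative edge jumps and Poisson noise at
protocol dose rates, with exact ground truth — on noise-free input the
three-window map cancels the background to machine precision, and the
thickness estimate inverts exactly. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Three 30 nm silica particles in 60 nm of vitreous ice, imaged at the
25k-magnification protocol (0.21 nm px, 7.6 e⁻/Å²/s, 4 s prepre and
20 s pre/core exposures, four drifting frames per exposure):

```python
import numpy as np
import cryoeels as ce
from cryoeels.particles import bin_image

px = 0.21
field = px * 512
spec = ce.SceneSpec(
    field_size=(field, field), pixel_size=px, ice_thickness=60.0,
    particles=[
        ce.ParticleSpec(center=(30, 35), radius=15, element="Si", coverage=0.33),
        ce.ParticleSpec(center=(70, 60), radius=15, element="Si", coverage=0.33),
        ce.ParticleSpec(center=(45, 85), radius=15, element="Si", coverage=0.33),
    ],
)
scene = ce.build_scene(spec)
triplet = ce.default_triplet("Si")           # 71 / 93 / 117 eV, 20 eV slit
acq = ce.AcquisitionSpec(
    windows=triplet,
    exposures={"zero_loss": 0.5, "prepre": 4.0, "pre": 20.0, "core": 20.0},
    dose_rate=7.6, frames_per_exposure=4, drift_per_frame=(0.5, 0.3),
)
images = ce.simulate_acquisition(scene, acq, seed=11)

prepre, _ = ce.align_and_sum(images["prepre"])
pre, _ = ce.align_and_sum(images["pre"])
core, trace = ce.align_and_sum(images["core"])
si_map = ce.three_window_map(prepre, pre, core, triplet, element="Si")

budget = ce.dose_budget(7.6, prepre=4, pre=20, precision=0)
rm = ce.estimate_exponent_map(prepre, pre, triplet, smooth_radius=2)
fg = scene.coverage["Si"] > 0.2
bg = ~(scene.coverage["Si"] > 0)
sb = ce.signal_to_background(core, fg, bg)
thick = ce.ice_thickness(
    bin_image(images["unfiltered"].pixels, 8), bin_image(images["zero_loss"].pixels, 8)
)
```

This prints:

```
total dose: 334 e-/A^2 over 44 s
recovered drift of last core frame: (0.7, 0.9) px
mean background exponent r: 3.00
Si map inside particles: 3.3 counts/px, background: -1.4
S/B on the raw core-loss image: 1.64
ice thickness (8x8-binned log-ratio): 64 nm
```

Reading the numbers: the dose budget matches the 30/50 nm silica
protocol row (7.6 × 44 s = 334 e⁻/Å²). The per-frame drift trace tracks
the simulated (0.5, 0.3) px/frame motion to within the shot-noise limit
of very low-count frames. The smoothed exponent map recovers the
simulated `r = 3.00`. The elemental map concentrates positive signal on
the particles (at ~3 counts per pixel — this is genuinely dose-limited
data; the small negative background offset is the documented low-count
bias of the per-pixel background constant). The log-ratio thickness on
8×8-binned images returns ≈ 64 nm for 60 nm ice plus the particles'
contribution within the field.

## Command line

A thin CLI wraps the same functions:

```
cryoeels simulate  --config demo.yaml --seed 7 --out out/
cryoeels map       --prepre out/prepre.tif --pre out/pre.tif --core out/core.tif \
                   --centers 71,93,117 --width 20 --out si_map.tif --mask si_mask.tif
cryoeels align     --stack stack.mrc --out sum.tif --trace trace.csv --upsample 10
cryoeels thickness --unfiltered un.tif --zeroloss zl.tif --mfp 400 --out t.tif
cryoeels particles --image zl.tif --pixel-size 0.21 --bin 4 --out particles.csv
cryoeels coloc     --zeroloss zl.tif --elmap si_map.tif --out-prefix out/coloc
cryoeels dose      --config table.yaml
```

Images are TIFF or MRC with a JSON metadata sidecar; spectra are
two-column text; every run echoes its parameters into a sidecar so it
can be reproduced from config + seed.

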