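"""Forward simulator for energy-filtered cryo-TEM scenes.

Produces zero-loss, unfiltered, and window-triplet images (plus 1-D
energy-loss spectra) of nanoparticles embedded in vitreous ice, with
known ground truth, so that every stage of the mapping pipeline can be
tested without real micrographs.

The model is phenomenological, not a physical cross-section model:

* the energy-loss background per pixel follows a power law
  ``I(E) = A * E**(-r)``, with the amplitude ``A`` proportional to the
  local mass thickness (ice + carbon film + particle) and the exponent
  ``r`` spatially constant by default;
* a core-loss edge multiplies the background by ``(1 + J * coverage)``
  at every energy at and above its onset — a flat multiplicative step.
  A step that is present in all three windows of a triplet cancels
  exactly in the three-window algebra, so only the edge whose onset
  falls between the pre and core window centres contributes signal,
  which is precisely the behaviour the window geometry is designed for;
* window-integrated intensity uses the centre-energy approximation
  (value at the window centre times the width), matching the way the
  background constants are defined from central energy-loss values;
* the zero-loss image is the unfiltered image attenuated by
  ``exp(-t/Lambda)`` with ``t`` the total local thickness, so the
  log-ratio thickness estimate holds by construction.  Dense particles
  and film additionally remove electrons from both images equally
  (objective-aperture loss), which gives the zero-loss image realistic
  particle contrast without perturbing the thickness ratio;
* detector gain is 1 count per electron and counts are Poisson.

All randomness flows from one explicit seed; per-image sub-streams are
spawned deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import (
    ELEMENT_EDGES,
    EnergyWindow,
    FilteredImage,
    FrameStack,
    WindowTriplet,
)

__all__ = [
    "ParticleSpec",
    "SceneSpec",
    "EdgeModel",
    "BackgroundModel",
    "AcquisitionSpec",
    "Scene",
    "default_edge_model",
    "build_scene",
    "expected_window_image",
    "true_jump_image",
    "expected_zero_loss",
    "expected_unfiltered",
    "simulate_acquisition",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class ParticleSpec:
    """One spherical particle: position and radius in nm.

    ``coverage`` is the fraction of the beam path occupied by the
    particle at its centre, in (0, 1]; the per-pixel coverage profile
    falls off as the spherical chord.
    """

    center: tuple[float, float]  # (x, y) nm
    radius: float  # nm
    element: str
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"particle radius must be > 0, got {self.radius}")
        if not 0 < self.coverage <= 1:
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic field of view.

    ``ice_thickness`` may be a scalar (nm) or a full-field map;
    ``film_region`` is an optional boolean mask marking where the
    amorphous carbon support film is present (adding ``film_thickness``
    nm of carbon).  ``mean_free_path`` is the inelastic mean free path
    used to attenuate the zero-loss image; ``elastic_mean_free_path``
    is a phenomenological aperture-loss length applied to the dense
    material (film + particles) in both the unfiltered and zero-loss
    images.
    """

    field_size: tuple[float, float]  # (width, height) nm
    pixel_size: float  # nm
    ice_thickness: float | np.ndarray = 100.0
    film_region: np.ndarray | None = None
    film_thickness: float = 20.0
    particles: list[ParticleSpec] = field(default_factory=list)
    mean_free_path: float = 400.0
    elastic_mean_free_path: float = 100.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(np.asarray(self.ice_thickness) < 0):
            raise ValueError("ice_thickness must be >= 0 everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.field_size
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))


@dataclass(frozen=True)
class EdgeModel:
    """Core-loss edge of one element in the phenomenological model.

    ``jump_ratio`` is the relative elevation of the post-edge intensity
    over the local power-law background where the element fully covers
    the beam path.
    """

    element: str
    onset: float  # eV
    jump_ratio: float
    window_width: float

    def __post_init__(self) -> None:
        if not self.onset > 0:
            raise ValueError("edge onset must be > 0 eV")
        if self.jump_ratio < 0:
            raise ValueError("jump_ratio must be >= 0")


# Default edge jump ratios.  These are model assumptions, not measured
# quantities: they are calibrated so that a 10 nm silica particle in
# ~60 nm of ice sits at the margin of detectability at the dose budget
# of the imaging protocol, which is where the real method operates.
# Relative magnitudes follow the qualitative edge strengths seen in
# cryo-EELS spectra (the Ca-L2,3 white lines are sharp and strong, the
# P-L2,3 edge weak and plasmon-embedded).
DEFAULT_JUMP_RATIOS: dict[str, float] = {
    "Si": 0.6,
    "P": 0.4,
    "C": 0.5,
    "Ca": 0.8,
    "O": 0.7,
}


def default_edge_model(element: str) -> EdgeModel:
    edge = ELEMENT_EDGES[element]
    return EdgeModel(
        element=element,
        onset=edge["onset"],
        jump_ratio=DEFAULT_JUMP_RATIOS[element],
        window_width=edge["width"],
    )


@dataclass(frozen=True)
class BackgroundModel:
    """Power-law background parameters.

    ``amplitude_per_nm`` is the amplitude A per nm of local thickness,
    in units of (fraction of incident electrons) * eV**r, so that the
    expected fraction of electrons detected in a window of width w at
    centre E over thickness t is ``amplitude_per_nm * t * E**(-r) * w``.
    The default places ~3% of the beam in a 20 eV window at 117 eV over
    60 nm of ice.
    """

    amplitude_per_nm: float = 40.0
    exponent: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude_per_nm < 0:
            raise ValueError("amplitude must be >= 0")
        if not math.isfinite(self.exponent):
            raise ValueError("exponent must be finite")


@dataclass
class Scene:
    """Rasterized ground truth for a synthetic field of view."""

    pixel_size: float  # nm
    thickness: np.ndarray  # total local thickness, nm
    ice_thickness: np.ndarray  # nm
    coverage: dict[str, np.ndarray]  # per-element beam-path coverage
    amplitude: np.ndarray  # power-law A per pixel
    exponent: np.ndarray  # power-law r per pixel
    edges: dict[str, EdgeModel]
    elastic_loss: np.ndarray  # aperture-loss optical depth, dimensionless
    mean_free_path: float  # inelastic, nm
    film_mask: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness.shape  # type: ignore[return-value]


def build_scene(
    spec: SceneSpec,
    edges: dict[str, EdgeModel] | None = None,
    background: BackgroundModel | None = None,
) -> Scene:
    """Rasterize a scene specification onto the pixel grid.

    Pixel centres sit at integer pixel coordinates; physical position of
    pixel (i, j) is (x, y) = (j, i) * pixel_size nm.  Raises if a
    particle extends outside the field, naming the particle.
    """
    background = background or BackgroundModel()
    shape = spec.shape
    ny, nx = shape
    px = spec.pixel_size
    w_nm, h_nm = (nx - 1) * px, (ny - 1) * px

    ice = np.broadcast_to(
        np.asarray(spec.ice_thickness, dtype=np.float64), shape
    ).copy()
    thickness = ice.copy()
    elastic_loss = np.zeros(shape)

    film_mask = None
    if spec.film_region is not None:
        film_mask = np.asarray(spec.film_region, dtype=bool)
        if film_mask.shape != shape:
            raise ValueError("film_region mask shape differs from scene shape")
        thickness += film_mask * spec.film_thickness
        elastic_loss += film_mask * (spec.film_thickness / spec.elastic_mean_free_path)

    edge_models: dict[str, EdgeModel] = dict(edges) if edges else {}
    coverage: dict[str, np.ndarray] = {}
    if film_mask is not None:
        # The support film is amorphous carbon: it carries C coverage.
        edge_models.setdefault("C", default_edge_model("C"))
        coverage["C"] = film_mask.astype(np.float64)

    yy, xx = np.mgrid[0:ny, 0:nx]
    xx_nm = xx * px
    yy_nm = yy * px

    for i, p in enumerate(spec.particles):
        cx, cy = p.center
        if (
            cx - p.radius < 0
            or cx + p.radius > w_nm
            or cy - p.radius < 0
            or cy + p.radius > h_nm
        ):
            raise ValueError(
                f"particle {i} ({p.element}, r={p.radius} nm at {p.center}) "
                "extends outside the field of view"
            )
        if p.element not in edge_models:
            if p.element in ELEMENT_EDGES:
                edge_models[p.element] = default_edge_model(p.element)
            else:
                raise ValueError(
                    f"particle {i}: no edge model for element {p.element!r}"
                )
        d2 = (xx_nm - cx) ** 2 + (yy_nm - cy) ** 2
        inside = d2 <= p.radius**2
        # Spherical chord through the particle at each pixel, nm.
        chord = np.zeros(shape)
        chord[inside] = 2.0 * np.sqrt(p.radius**2 - d2[inside])
        profile = np.zeros(shape)
        profile[inside] = p.coverage * np.sqrt(
            np.clip(1.0 - d2[inside] / p.radius**2, 0.0, 1.0)
        )
        thickness += chord
        elastic_loss += chord / spec.elastic_mean_free_path
        cov = coverage.setdefault(p.element, np.zeros(shape))
        np.maximum(cov, profile, out=cov)

    amplitude = background.amplitude_per_nm * thickness
    exponent = np.full(shape, background.exponent)

    return Scene(
        pixel_size=px,
        thickness=thickness,
        ice_thickness=ice,
        coverage=coverage,
        amplitude=amplitude,
        exponent=exponent,
        edges=edge_models,
        elastic_loss=elastic_loss,
        mean_free_path=spec.mean_free_path,
        film_mask=film_mask,
    )


def _jump_factor(scene: Scene, energy: float) -> np.ndarray:
    """Multiplicative edge factor (1 + sum of J * coverage) at an energy."""
    factor = np.ones(scene.shape)
    for el, cov in scene.coverage.items():
        edge = scene.edges[el]
        if energy >= edge.onset:
            factor += edge.jump_ratio * cov
    return factor


def expected_window_image(scene: Scene, window: EnergyWindow) -> np.ndarray:
    """Expected detected fraction of incident electrons per pixel.

    Centre-energy approximation: background = A * E_c**(-r) * width,
    multiplied by (1 + J * coverage) for every edge with onset at or
    below the window centre.  Multiply by dose (e-/A^2) and pixel area
    (A^2) to get expected counts.
    """
    if not window.center > 0:
        raise ValueError("window centre must be > 0 eV")
    bg = scene.amplitude * window.center ** (-scene.exponent) * window.width
    return bg * _jump_factor(scene, window.center)


def true_jump_image(scene: Scene, triplet: WindowTriplet) -> np.ndarray:
    """Ground-truth elemental signal for a window triplet.

    The jump term that the three-window method should recover: the sum
    over elements whose onset lies in (pre centre, core centre] of
    J * coverage * background(core).  Exact provided no edge onset falls
    between the prepre and pre window centres (a mis-chosen triplet).
    """
    bg_core = (
        scene.amplitude * triplet.core.center ** (-scene.exponent) * triplet.core.width
    )
    signal = np.zeros(scene.shape)
    for el, cov in scene.coverage.items():
        edge = scene.edges[el]
        if triplet.pre.center < edge.onset <= triplet.core.center:
            signal += edge.jump_ratio * cov * bg_core
    return signal


def expected_unfiltered(scene: Scene) -> np.ndarray:
    """Expected unfiltered transmitted fraction per pixel."""
    return np.exp(-scene.elastic_loss)


def expected_zero_loss(scene: Scene) -> np.ndarray:
    """Expected zero-loss fraction: unfiltered times exp(-t/Lambda)."""
    return expected_unfiltered(scene) * np.exp(-scene.thickness / scene.mean_free_path)


@dataclass
class AcquisitionSpec:
    """Exposure plan for one window-triplet acquisition.

    ``exposures`` maps the images to their exposure times in seconds
    (keys: zero_loss, prepre, pre, core; unfiltered reuses zero_loss).
    ``drift_per_frame`` is the (dy, dx) pixel drift accumulated between
    consecutive dose-fractionated frames; ``window_shifts`` optionally
    misaligns whole window images relative to the zero-loss template.
    """

    windows: WindowTriplet
    exposures: dict[str, float]
    dose_rate: float  # e-/A^2/s
    slit_width: float | None = None
    frames_per_exposure: int = 1
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    window_shifts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_rate < 0:
            raise ValueError("dose_rate must be >= 0")
        if self.frames_per_exposure < 1:
            raise ValueError("frames_per_exposure must be >= 1")
        for key, t in self.exposures.items():
            if t < 0:
                raise ValueError(f"exposure {key!r} must be >= 0, got {t}")


def _shift_expected(expected: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    dy, dx = shift
    if dy == 0 and dx == 0:
        return expected
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.roll(expected, (int(dy), int(dx)), axis=(0, 1))
    else:
        out = ndimage.shift(expected, (dy, dx), order=1, mode="nearest")
    return out


def _poisson_image(
    rng: np.random.Generator, expected: np.ndarray, dose: float, pixel_area_a2: float
) -> np.ndarray:
    mean = expected * dose * pixel_area_a2
    return rng.poisson(mean).astype(np.float64)


def simulate_acquisition(
    scene: Scene, acq: AcquisitionSpec, seed: int
) -> dict[str, FilteredImage | FrameStack]:
    """Simulate one full three-window acquisition of a scene.

    Returns a dict with keys ``zero_loss``, ``unfiltered`` (single
    :class:`FilteredImage` each) and ``prepre``, ``pre``, ``core``
    (:class:`FrameStack` of ``frames_per_exposure`` dose-fractionated
    frames, drifting by ``drift_per_frame`` per frame).  Counts are
    Poisson with mean = expected fraction x dose_rate x frame exposure x
    pixel area (A^2); a zero dose yields all-zero images.
    """
    px_area = (scene.pixel_size * 10.0) ** 2  # nm -> Angstrom, squared
    streams = np.random.SeedSequence(seed).spawn(5)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(["zero_loss", "unfiltered", "prepre", "pre", "core"], streams)
    }
    windows = {
        "prepre": acq.windows.prepre,
        "pre": acq.windows.pre,
        "core": acq.windows.core,
    }
    out: dict[str, FilteredImage | FrameStack] = {}

    for name, expected in [
        ("zero_loss", expected_zero_loss(scene)),
        ("unfiltered", expected_unfiltered(scene)),
    ]:
        exp_t = acq.exposures.get("zero_loss", 0.0)
        shifted = _shift_expected(expected, acq.window_shifts.get(name, (0.0, 0.0)))
        counts = _poisson_image(rngs[name], shifted, acq.dose_rate * exp_t, px_area)
        out[name] = FilteredImage(
            pixels=counts,
            window=name.replace("_", "-"),
            exposure=exp_t,
            dose_rate=acq.dose_rate,
            pixel_size=scene.pixel_size,
        )

    dy0, dx0 = acq.drift_per_frame
    for name, window in windows.items():
        exp_t = acq.exposures.get(name, 0.0)
        frame_t = exp_t / acq.frames_per_exposure
        expected = expected_window_image(scene, window)
        base = _shift_expected(expected, acq.window_shifts.get(name, (0.0, 0.0)))
        frames = []
        for i in range(acq.frames_per_exposure):
            shifted = _shift_expected(base, (i * dy0, i * dx0))
            frames.append(
                _poisson_image(rngs[name], shifted, acq.dose_rate * frame_t, px_area)
            )
        out[name] = FrameStack(
            frames=frames,
            frame_exposure=frame_t,
            window=window,
            dose_rate=acq.dose_rate,
            pixel_size=scene.pixel_size,
        )
    return out


def simulate_spectrum(
    energy: np.ndarray,
    *,
    background: BackgroundModel | None = None,
    thickness: float = 100.0,
    elements: list[tuple[EdgeModel, float]] | None = None,
    zero_loss_height: float = 1e5,
    zero_loss_sigma: float = 1.0,
    plasmon_height: float = 5e3,
    plasmon_center: float = 23.0,
    plasmon_sigma: float = 8.0,
    tail_onset: float = 15.0,
    tail_level: float | None = None,
    edge_sharpness: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a 1-D energy-loss spectrum.

    Model: a Gaussian zero-loss peak, a Gaussian plasmon bump, a
    power-law tail proportional to E**(-r) switched on smoothly above
    the plasmon region, and a sigmoidal step at each element's onset
    that raises the tail by J * coverage.  Poisson-sampled when a seed
    is given.

    ``tail_level`` sets the tail counts per channel at 100 eV; by
    default it scales with the zero-loss height and the thickness (a
    thicker specimen scatters more of the beam into the loss tail).
    The exponent comes from ``background``.

    ``energy`` must be strictly increasing (eV; may include <= 0 for the
    zero-loss region, where the power-law tail is zero).
    """
    energy = np.asarray(energy, dtype=np.float64)
    if energy.ndim != 1 or energy.size < 2 or np.any(np.diff(energy) <= 0):
        raise ValueError("energy axis must be 1-D and strictly increasing")
    background = background or BackgroundModel()
    r = background.exponent
    if tail_level is None:
        tail_level = 2e-3 * zero_loss_height * thickness / 100.0

    spectrum = zero_loss_height * np.exp(-(energy**2) / (2 * zero_loss_sigma**2))
    spectrum += plasmon_height * np.exp(
        -((energy - plasmon_center) ** 2) / (2 * plasmon_sigma**2)
    )
    e_safe = np.clip(energy, 1.0, None)
    ramp = 1.0 / (1.0 + np.exp(-(energy - tail_onset) / 3.0))
    tail = tail_level * (e_safe / 100.0) ** (-r) * ramp
    step = np.ones_like(energy)
    for edge, cov in elements or []:
        step += (
            edge.jump_ratio
            * cov
            / (1.0 + np.exp(-(energy - edge.onset) / edge_sharpness))
        )
    spectrum += tail * step
    if seed is None:
        return spectrum
    rng = np.random.default_rng(seed)
    return rng.poisson(spectrum).astype(np.float64)
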