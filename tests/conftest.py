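"""Shared fixtures: window geometries and synthetic phantom builders."""

from __future__ import annotations

import numpy as np
import pytest

import cryoeels as ce


@pytest.fixture
def si_triplet() -> ce.WindowTriplet:
    return ce.default_triplet("Si")


@pytest.fixture
def toy_triplet() -> ce.WindowTriplet:
    """The 200/250/300 eV geometry used in hand-derived examples."""
    return ce.WindowTriplet(
        prepre=ce.EnergyWindow(200.0, 20.0),
        pre=ce.EnergyWindow(250.0, 20.0),
        core=ce.EnergyWindow(300.0, 20.0),
    )


@pytest.fixture
def flat_scene() -> ce.Scene:
    """A featureless 60 nm ice field, 64x64 px at 0.21 nm."""
    spec = ce.SceneSpec(
        field_size=(0.21 * 64, 0.21 * 64), pixel_size=0.21, ice_thickness=60.0
    )
    return ce.build_scene(spec)


def make_disk_image(
    disks: list[tuple[float, float, float]],
    field_nm: float,
    pixel_size: float = 0.21,
    base: float = 1000.0,
    depth: float = 500.0,
) -> np.ndarray:
    """Flat-contrast phantom: dark disks (cx, cy, diameter) nm on a
    bright background, as a zero-loss image of opaque particles."""
    n = int(round(field_nm / pixel_size))
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.full((n, n), base)
    for cx, cy, d in disks:
        inside = ((xx * pixel_size - cx) ** 2 + (yy * pixel_size - cy) ** 2) <= (d / 2) ** 2
        img[inside] = base - depth
    return img


@pytest.fixture
def disk_image_factory():
    return make_disk_image


def make_particle_scene(
    n_side: int = 4,
    radius_nm: float = 5.0,
    element: str = "Si",
    ice_nm: float = 60.0,
    npx: int = 768,
    pixel_size: float = 0.21,
    coverage: float | None = None,
    jitter_seed: int = 12345,
) -> ce.Scene:
    """Grid of jittered particles in flat ice — the detection-limit scene."""
    field = pixel_size * npx
    rng = np.random.default_rng(jitter_seed)
    if coverage is None:
        coverage = 2 * radius_nm / (ice_nm + 2 * radius_nm)
    particles = [
        ce.ParticleSpec(
            center=(
                field * (i + 0.5) / n_side + rng.uniform(-6, 6),
                field * (j + 0.5) / n_side + rng.uniform(-6, 6),
            ),
            radius=radius_nm,
            element=element,
            coverage=coverage,
        )
        for i in range(n_side)
        for j in range(n_side)
    ]
    spec = ce.SceneSpec(
        field_size=(field, field),
        pixel_size=pixel_size,
        ice_thickness=ice_nm,
        particles=particles,
    )
    return ce.build_scene(spec)


@pytest.fixture
def particle_scene_factory():
    return make_particle_scene
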