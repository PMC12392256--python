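"""Core containers for energy-filtered images and window geometry.

An energy-filtered (EF) image is acquired by letting only electrons with
energy loss inside a slit-selected window reach the detector.  The
three-window method uses three such windows per element: two below the
core-loss edge onset (*prepre* and *pre*) to fit the decaying background,
and one straddling / above the onset (*core*) that carries the elemental
signal.  Coordinate convention throughout the package: arrays are
row-major with origin at the top-left, pixel centres at integer
coordinates, and shifts reported as ``(dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EnergyWindow",
    "WindowTriplet",
    "FilteredImage",
    "FrameStack",
    "ELEMENT_EDGES",
    "default_triplet",
]


@dataclass(frozen=True)
class EnergyWindow:
    """An energy-loss acceptance window.

    Parameters
    ----------
    center : float
        Central energy loss of the window, eV.
    width : float
        Slit width, eV.
    """

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")
        if not self.center - self.width / 2 > 0:
            raise ValueError(
                f"window [{self.center} +/- {self.width / 2}] eV extends to "
                "non-positive energy loss"
            )

    @property
    def lo(self) -> float:
        return self.center - self.width / 2

    @property
    def hi(self) -> float:
        return self.center + self.width / 2


@dataclass(frozen=True)
class WindowTriplet:
    """The prepre/pre/core window geometry of the three-window method.

    The two pre-edge windows must share a width so their summed
    intensities are directly comparable in the power-law exponent
    estimate; centres must be strictly increasing.
    """

    prepre: EnergyWindow
    pre: EnergyWindow
    core: EnergyWindow

    def __post_init__(self) -> None:
        if not (self.prepre.center < self.pre.center < self.core.center):
            raise ValueError(
                "window centres must satisfy prepre < pre < core, got "
                f"{self.prepre.center}, {self.pre.center}, {self.core.center}"
            )
        if self.prepre.width != self.pre.width:
            raise ValueError(
                "prepre and pre windows must share a width, got "
                f"{self.prepre.width} and {self.pre.width}"
            )

    @property
    def centers(self) -> tuple[float, float, float]:
        return (self.prepre.center, self.pre.center, self.core.center)


ZERO_LOSS = "zero-loss"
UNFILTERED = "unfiltered"


@dataclass
class FilteredImage:
    """A 2-D counts image with its acquisition metadata.

    ``window`` is an :class:`EnergyWindow` for energy-filtered images, or
    one of the tags ``"zero-loss"`` / ``"unfiltered"``.  ``valid`` marks
    pixels that carry trustworthy counts (e.g. not shifted in from
    outside the field of view); ``None`` means all pixels valid.
    """

    pixels: np.ndarray
    window: EnergyWindow | str | None = None
    exposure: float = 0.0
    dose_rate: float = 0.0
    pixel_size: float = 0.0  # nm
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixel values")
        if self.exposure < 0:
            raise ValueError("exposure must be >= 0")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.pixels.shape:
                raise ValueError("validity mask shape differs from image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def validity(self) -> np.ndarray:
        """Validity mask, materialised (all-true when unset)."""
        if self.valid is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.valid

    def with_pixels(self, pixels: np.ndarray, valid: np.ndarray | None = None) -> "FilteredImage":
        return replace(self, pixels=pixels, valid=valid if valid is not None else self.valid)


@dataclass
class FrameStack:
    """An ordered stack of dose-fractionated frames from one exposure."""

    frames: list[np.ndarray] = field(default_factory=list)
    frame_exposure: float = 0.0
    window: EnergyWindow | str | None = None
    dose_rate: float = 0.0
    pixel_size: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a frame stack needs at least one frame")
        self.frames = [np.asarray(f, dtype=np.float64) for f in self.frames]
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2 or f.shape != shape:
                raise ValueError(f"frame {i} shape {f.shape} differs from {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape  # type: ignore[return-value]

    @property
    def total_exposure(self) -> float:
        return self.frame_exposure * len(self.frames)

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


# Core-loss edge onsets (eV) and the slit widths used per element:
# 15 eV for P and Ca, 20 eV for O and Si, 40 eV for C.
ELEMENT_EDGES: dict[str, dict[str, float]] = {
    "Si": {"onset": 105.0, "width": 20.0},  # Si-L2,3
    "P": {"onset": 136.0, "width": 15.0},   # P-L2,3
    "C": {"onset": 285.0, "width": 40.0},   # C-K
    "Ca": {"onset": 347.0, "width": 15.0},  # Ca-L2,3
    "O": {"onset": 532.0, "width": 20.0},   # O-K
}


def default_triplet(element: str, gap: float = 2.0) -> WindowTriplet:
    """Standard window triplet for an element's core-loss edge.

    The core window sits just above the onset, the pre window just
    below, and the prepre window one window-width further down, with a
    small guard ``gap`` (eV) between adjacent windows.
    """
    try:
        edge = ELEMENT_EDGES[element]
    except KeyError:
        raise KeyError(
            f"unknown element {element!r}; known: {sorted(ELEMENT_EDGES)}"
        ) from None
    w = edge["width"]
    onset = edge["onset"]
    core = EnergyWindow(onset + w / 2 + gap, w)
    pre = EnergyWindow(onset - w / 2 - gap, w)
    prepre = EnergyWindow(pre.center - w - gap, w)
    return WindowTriplet(prepre=prepre, pre=pre, core=core)
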