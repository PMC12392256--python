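"""Three-window and two-window elemental-map computation.

The energy-loss background under a core-loss edge decays with energy
loss E as a power law, I(E) = A * E**(-r).  Sampling that background in
two pre-edge windows (prepre, pre) with equal widths determines the
exponent per pixel,

    r = (log Iw_P - log Iw_PP) / log(E_PP / E_P),

from which the background expected in the core window is k * Iw_P with
k = (E_C / E_P) ** (-r).  The elemental map is the residual

    map = Image_C - k * Image_P.

The two-window variant subtracts the pre-edge image directly and is
biased low-side because the background keeps decaying between the pre
and core windows.  All operations are per pixel on window-integrated
intensities, carry a validity mask, and retain negative residuals (any
clipping is a display/export concern, not a mapping one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import FilteredImage, WindowTriplet

__all__ = [
    "ExponentMap",
    "ElementMap",
    "estimate_exponent_map",
    "power_law_amplitude",
    "background_constant_map",
    "three_window_map",
    "two_window_map",
]


@dataclass
class ExponentMap:
    """Per-pixel power-law exponent r with its validity mask."""

    r: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r.shape != self.valid.shape:
            raise ValueError("exponent and mask shapes differ")


@dataclass
class ElementMap:
    """A background-subtracted core-loss image.

    ``values`` may be negative (noise); ``k_map`` is the per-pixel
    background constant that was applied (all-ones for the two-window
    method).
    """

    values: np.ndarray
    valid: np.ndarray
    element: str = ""
    k_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and mask shapes differ")


def _as_pixels(img: FilteredImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(img, FilteredImage):
        return img.pixels, img.validity()
    arr = np.asarray(img, dtype=np.float64)
    return arr, np.ones(arr.shape, dtype=bool)


def _exposure(img: FilteredImage | np.ndarray) -> float:
    """Exposure scale of an image; 1.0 when unknown (plain arrays).

    Window exposures differ in practice (the pre/core windows get several
    times the prepre exposure), so raw counts are not on a common
    intensity scale: the power-law fit must compare counts per second.
    """
    if isinstance(img, FilteredImage) and img.exposure > 0:
        return img.exposure
    return 1.0


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"input images have mismatched shapes: {sorted(shapes)}")


def estimate_exponent_map(
    prepre: FilteredImage | np.ndarray,
    pre: FilteredImage | np.ndarray,
    triplet: WindowTriplet,
    *,
    intensity_floor: float = 1.0,
    r_bounds: tuple[float, float] = (-10.0, 10.0),
    smooth_radius: int = 0,
) -> ExponentMap:
    """Per-pixel power-law exponent from the two pre-edge images.

    Pixels where either input's raw counts are at or below
    ``intensity_floor`` are masked invalid rather than clamped: at low
    dose a clamped logarithm fabricates an exponent where there is no
    information.  Exponents outside ``r_bounds`` (hot/dead pixels) are
    likewise masked.  ``smooth_radius`` > 0 applies a boxcar mean of
    that radius to both inputs first; off by default.

    When the inputs carry exposure metadata, counts are normalised to
    counts per second before the log-ratio — the prepre and pre windows
    are usually acquired with different exposures.
    """
    ipp, vpp = _as_pixels(prepre)
    ip, vp = _as_pixels(pre)
    _check_shapes(ipp, ip)
    e_pp, e_p = triplet.prepre.center, triplet.pre.center
    if e_pp == e_p:
        raise ValueError("degenerate geometry: E_PP == E_P")

    if smooth_radius > 0:
        size = 2 * smooth_radius + 1
        ipp = ndimage.uniform_filter(ipp, size=size, mode="nearest")
        ip = ndimage.uniform_filter(ip, size=size, mode="nearest")

    valid = vpp & vp & (ipp > intensity_floor) & (ip > intensity_floor)
    r = np.zeros_like(ipp)
    denom = np.log(e_pp / e_p)
    # exposure normalisation shifts both logs by a constant
    offset = np.log(_exposure(pre) / _exposure(prepre))
    with np.errstate(divide="ignore", invalid="ignore"):
        r[valid] = (np.log(ip[valid]) - np.log(ipp[valid]) - offset) / denom
    lo, hi = r_bounds
    in_bounds = (r >= lo) & (r <= hi)
    valid &= in_bounds
    r[~valid] = 0.0
    return ExponentMap(r=r, valid=valid)


def power_law_amplitude(
    intensity: FilteredImage | np.ndarray,
    center: float,
    exponent: ExponentMap | np.ndarray,
) -> np.ndarray:
    """Power-law amplitude A = Iw * E**r from one window's intensity.

    Computed from the prepre window and from the pre window, A must
    agree wherever the exponent is valid — a built-in consistency check
    on the two-point fit.  Intensities with exposure metadata are
    normalised to counts per second first.  Invalid pixels are NaN.
    """
    iw, vi = _as_pixels(intensity)
    iw = iw / _exposure(intensity)
    if isinstance(exponent, ExponentMap):
        r, valid = exponent.r, exponent.valid & vi
    else:
        r = np.asarray(exponent, dtype=np.float64)
        valid = vi
    _check_shapes(iw, r)
    amp = np.full_like(iw, np.nan)
    amp[valid] = iw[valid] * center ** r[valid]
    return amp


def background_constant_map(
    exponent: ExponentMap, triplet: WindowTriplet
) -> np.ndarray:
    """Background constant k = (E_C / E_P)**(-r), per pixel.

    For r >= 0 and E_C > E_P, k lies in (0, 1]: the background can only
    decay between the pre and core windows.  Invalid pixels are NaN.
    """
    ratio = triplet.core.center / triplet.pre.center
    k = np.full_like(exponent.r, np.nan)
    k[exponent.valid] = ratio ** (-exponent.r[exponent.valid])
    return k


def three_window_map(
    prepre: FilteredImage | np.ndarray,
    pre: FilteredImage | np.ndarray,
    core: FilteredImage | np.ndarray,
    triplet: WindowTriplet,
    *,
    element: str = "",
    intensity_floor: float = 1.0,
    r_bounds: tuple[float, float] = (-10.0, 10.0),
    smooth_radius: int = 0,
) -> ElementMap:
    """Elemental map by power-law background extrapolation.

    map = Image_C - k * Image_P with k from the per-pixel two-point fit.
    Inputs must already be mutually aligned (see `cryoeels.align`).
    Negative residuals are retained; validity is the intersection of the
    input masks and the exponent-fit mask.  If the pre and core images
    were acquired with different exposures, the pre image is rescaled to
    the core exposure before subtraction (the protocol normally gives
    them the same exposure, making the factor 1).
    """
    ipp, vpp = _as_pixels(prepre)
    ip, vp = _as_pixels(pre)
    ic, vc = _as_pixels(core)
    _check_shapes(ipp, ip, ic)
    rmap = estimate_exponent_map(
        prepre, pre, triplet,
        intensity_floor=intensity_floor, r_bounds=r_bounds,
        smooth_radius=smooth_radius,
    )
    k = background_constant_map(rmap, triplet)
    scale = _exposure(core) / _exposure(pre)
    valid = rmap.valid & vpp & vp & vc
    values = np.zeros_like(ic)
    values[valid] = ic[valid] - k[valid] * ip[valid] * scale
    return ElementMap(values=values, valid=valid, element=element, k_map=k)


def two_window_map(
    pre: FilteredImage | np.ndarray,
    core: FilteredImage | np.ndarray,
    *,
    element: str = "",
) -> ElementMap:
    """Elemental map by direct subtraction, map = Image_C - Image_P.

    The baseline the three-window method improves on: with a decaying
    background the residual is systematically negative over pure
    background.
    """
    ip, vp = _as_pixels(pre)
    ic, vc = _as_pixels(core)
    _check_shapes(ip, ic)
    valid = vp & vc
    values = ic - ip * (_exposure(core) / _exposure(pre))
    values[~valid] = 0.0
    k = np.ones_like(ip)
    return ElementMap(values=values, valid=valid, element=element, k_map=k)
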