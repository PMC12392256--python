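"""Translation registration for dose-fractionated frames and window series.

Two alignment problems arise in energy-filtered acquisition: stage/beam
drift *within* one exposure (corrected by aligning dose-fractionated
frames before summation) and drift *between* exposures at different
energy windows (corrected by registering each window image to a saved
zero-loss template).  Both are pure translations here: drift at a cooled
stage is small and slow, and rotation/scale changes are out of scope.

Registration uses upsampled phase cross-correlation.  Shifts are
reported as (dy, dx), the displacement of the image content *relative
to* the template: an image whose content sits 3 px lower than the
template reports dy = +3, and is aligned by shifting it (-3, 0).
Shifted-out border pixels are zero-filled and excluded via the validity
mask so no intensity is fabricated at edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.registration import phase_cross_correlation

from .images import FilteredImage, FrameStack

__all__ = [
    "DriftVector",
    "register_translation",
    "apply_shift",
    "align_and_sum",
    "align_window_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftVector:
    """A measured translation (pixels) with its correlation quality."""

    dy: float
    dx: float
    peak_score: float = 0.0

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dy, self.dx))


def _pixels(img: FilteredImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, FilteredImage) else np.asarray(img, float)


def register_translation(
    image: FilteredImage | np.ndarray,
    template: FilteredImage | np.ndarray,
    upsample: int = 10,
    smooth_sigma: float = 0.0,
) -> DriftVector:
    """Measure the translation of ``image`` relative to ``template``.

    Subpixel precision is 1/upsample.  ``smooth_sigma`` > 0 Gaussian
    low-pass filters both inputs before correlating — essential for
    dose-limited frames whose per-pixel counts are in the single digits,
    where shot noise otherwise dominates the correlation surface (a
    Gaussian filter commutes with translation, so the measured shift is
    unbiased).  Raises on flat (zero-variance) input, which carries no
    registration signal.
    """
    img = _pixels(image)
    tmpl = _pixels(template)
    if img.shape != tmpl.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {tmpl.shape}")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(img) == 0 or np.ptp(tmpl) == 0:
        raise ValueError("no signal to register (flat image)")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
        tmpl = ndimage.gaussian_filter(tmpl, smooth_sigma)
    shift, error, _ = phase_cross_correlation(
        tmpl, img, upsample_factor=upsample, normalization=None
    )
    # phase_cross_correlation returns the shift to apply to the moving
    # image; the displacement of the content is its negative.
    return DriftVector(dy=float(-shift[0]), dx=float(-shift[1]), peak_score=float(1.0 - error))


def apply_shift(
    image: np.ndarray, shift: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Translate an image by (dy, dx), zero-filling uncovered borders.

    Integer shifts are exact translations; fractional shifts use
    Fourier-domain shifting (exact for band-limited content).  Returns
    the shifted image and a boolean mask of pixels whose value did not
    come from outside the field of view.
    """
    dy, dx = float(shift[0]), float(shift[1])
    arr = np.asarray(image, dtype=np.float64)
    ny, nx = arr.shape
    valid = np.ones(arr.shape, dtype=bool)

    def _mask_border(mask: np.ndarray, d: float, axis: int) -> None:
        n = int(np.ceil(abs(d)))
        if n == 0:
            return
        sl = [slice(None), slice(None)]
        sl[axis] = slice(0, n) if d > 0 else slice(-n, None)
        mask[tuple(sl)] = False

    if dy.is_integer() and dx.is_integer():
        out = np.roll(arr, (int(dy), int(dx)), axis=(0, 1))
    else:
        out = np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(arr), (dy, dx))))
    _mask_border(valid, dy, axis=0)
    _mask_border(valid, dx, axis=1)
    out[~valid] = 0.0
    return out, valid


def align_and_sum(
    stack: FrameStack, upsample: int = 10, smooth_sigma: float = 2.0
) -> tuple[FilteredImage, list[DriftVector]]:
    """Register dose-fractionated frames to the first frame and sum.

    Frames that fail registration (no signal) fall back to the previous
    frame's shift, logged.  The returned drift trace has one entry per
    frame after the first (the reference); the summed image's exposure
    is the stack total and its validity mask excludes pixels any frame
    shifted in from outside.  ``smooth_sigma`` is the registration
    low-pass width (dose-fractionated frames are individually very
    noisy); it affects shift measurement only, never the summed counts.
    """
    reference = stack.frames[0]
    total = reference.copy()
    valid = np.ones(reference.shape, dtype=bool)
    trace: list[DriftVector] = []
    prev = DriftVector(0.0, 0.0, 1.0)
    for i, frame in enumerate(stack.frames[1:], start=1):
        try:
            drift = register_translation(frame, reference, upsample, smooth_sigma)
        except ValueError as exc:
            logger.warning(
                "frame %d registration failed (%s); reusing previous shift", i, exc
            )
            drift = DriftVector(prev.dy, prev.dx, 0.0)
        trace.append(drift)
        prev = drift
        aligned, mask = apply_shift(frame, (-drift.dy, -drift.dx))
        total += aligned
        valid &= mask
    return (
        FilteredImage(
            pixels=total,
            window=stack.window,
            exposure=stack.total_exposure,
            dose_rate=stack.dose_rate,
            pixel_size=stack.pixel_size,
            valid=valid,
        ),
        trace,
    )


def align_window_series(
    template: FilteredImage | np.ndarray,
    images: dict[str, FilteredImage],
    upsample: int = 10,
    max_shift: float | None = None,
    use_gradient: bool = True,
    smooth_sigma: float = 2.0,
) -> tuple[dict[str, FilteredImage], dict[str, DriftVector]]:
    """Register each window image to the zero-loss template.

    By default registration runs on Sobel gradient magnitudes of
    low-pass-filtered images: gradient magnitude is invariant to the
    contrast inversion between zero-loss images (particles dark) and
    energy-filtered images (particles bright), and the low-pass
    suppresses shot noise.  ``max_shift`` defaults to a quarter of the
    smaller image dimension; a larger measured shift indicates
    registration failure and raises, naming the offending window.
    """
    tmpl = _pixels(template)
    if max_shift is None:
        max_shift = min(tmpl.shape) / 4.0

    def _features(arr: np.ndarray) -> np.ndarray:
        if smooth_sigma > 0:
            arr = ndimage.gaussian_filter(arr, smooth_sigma)
        return sobel(arr) if use_gradient else arr

    tmpl_reg = _features(tmpl)
    aligned: dict[str, FilteredImage] = {}
    shifts: dict[str, DriftVector] = {}
    for name, img in images.items():
        arr = img.pixels
        if arr.shape != tmpl.shape:
            raise ValueError(
                f"window {name!r}: shape {arr.shape} differs from template {tmpl.shape}"
            )
        drift = register_translation(_features(arr), tmpl_reg, upsample)
        if max(abs(drift.dy), abs(drift.dx)) > max_shift:
            raise ValueError(
                f"window {name!r}: measured shift ({drift.dy:.2f}, {drift.dx:.2f}) "
                f"exceeds max_shift={max_shift:.2f} px; registration failure"
            )
        shifts[name] = drift
        moved, mask = apply_shift(arr, (-drift.dy, -drift.dx))
        aligned[name] = img.with_pixels(moved, valid=img.validity() & mask)
    return aligned, shifts
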