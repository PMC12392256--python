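"""Particle morphometry and two-channel colocalization.

Two pipelines, mirroring how zero-loss and elemental-map images are
analysed in practice:

* ``size_distribution`` — contrast enhancement (block binning, median
  filter, rolling-ball background subtraction, 8-bit conversion,
  binarization), watershed splitting of touching particles, then
  per-particle morphometry (area, ellipse axes, circularity) in nm.

* ``enhance_small_particle_images`` — the small-particle (10 nm)
  procedure: heavier binning and Gaussian blurring of the zero-loss and
  elemental-map channels, inversion of the zero-loss channel (particles
  are dark there), binarization of both, and superposition of the masks
  to confirm detections.

Binning is block-sum by default: counts are additive and summing
preserves Poisson statistics (a mean option exists for display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure, morphology, restoration, segmentation
from skimage.feature import peak_local_max
from skimage.measure import block_reduce

from .images import FilteredImage

__all__ = [
    "ParticleRecord",
    "MaskPair",
    "bin_image",
    "size_distribution",
    "enhance_small_particle_images",
    "overlap_stats",
]


@dataclass(frozen=True)
class ParticleRecord:
    """Morphometry of one segmented particle.

    ``centroid`` is (x, y) in binned pixels; ``area`` in binned px^2;
    axis lengths come from the ellipse with the component's second
    moments and are reported in nm via the binned pixel size.
    Circularity is 4*pi*area/perimeter^2, 1 for a perfect disk (up to
    discretization; values slightly above 1 can occur on small blobs).
    """

    label: int
    centroid: tuple[float, float]
    area: float
    major_axis: float  # nm
    minor_axis: float  # nm
    circularity: float


def bin_image(image: np.ndarray, factor: int, how: str = "sum") -> np.ndarray:
    """Block-bin a 2-D image by an integer factor (trailing rows/columns
    that do not fill a block are dropped, so each dimension shrinks to
    exactly floor(n/factor))."""
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    arr = np.asarray(image, dtype=np.float64)
    ny, nx = arr.shape
    arr = arr[: (ny // factor) * factor, : (nx // factor) * factor]
    func = {"sum": np.sum, "mean": np.mean}[how]
    return block_reduce(arr, (factor, factor), func)


def _to_uint8(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to the 8-bit range (constant images map to 0)."""
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return exposure.rescale_intensity(image, in_range=(lo, hi), out_range=(0, 255)).astype(np.uint8)


def _binarize(image8: np.ndarray, threshold: str | float) -> np.ndarray:
    if isinstance(threshold, (int, float)):
        return image8 > threshold
    if image8.min() == image8.max():
        return np.zeros(image8.shape, dtype=bool)
    method = {
        "otsu": filters.threshold_otsu,
        "isodata": filters.threshold_isodata,
        "triangle": filters.threshold_triangle,
    }[threshold]
    return image8 > method(image8)


def size_distribution(
    image: FilteredImage | np.ndarray,
    pixel_size: float | None = None,
    *,
    bin_factor: int = 4,
    median_radius: int = 2,
    background_radius: float = 50.0,
    threshold: str | float = "otsu",
    min_area: int = 9,
    dark_particles: bool = True,
    watershed: bool = True,
    min_separation: int = 5,
) -> list[ParticleRecord]:
    """Segment and measure particles in a micrograph.

    Pipeline (in order): block binning, median filtering, inversion
    (zero-loss particles are darker than the surrounding ice, and the
    rolling ball must see them as foreground), rolling-ball background
    subtraction, 8-bit conversion, binarization, small-object removal,
    and watershed on the distance transform to split touching
    particles.  ``background_radius``, ``median_radius`` and
    ``min_separation`` are in binned pixels; the rolling-ball radius
    must exceed the largest particle radius or particle interiors are
    treated as background.  An all-background image yields an empty
    list.
    """
    if isinstance(image, FilteredImage):
        arr = image.pixels
        pixel_size = pixel_size if pixel_size is not None else image.pixel_size
    else:
        arr = np.asarray(image, dtype=np.float64)
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("a positive pixel_size (nm) is required")
    binned_px = pixel_size * bin_factor

    work = bin_image(arr, bin_factor)
    if work.min() == work.max():
        return []
    if median_radius > 0:
        work = filters.median(work, morphology.disk(median_radius))
    if dark_particles:
        work = work.max() - work
    if background_radius > 0:
        work = work - restoration.rolling_ball(work, radius=background_radius)
    img8 = _to_uint8(work)
    mask = _binarize(img8, threshold)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        return []

    if watershed:
        distance = ndimage.distance_transform_edt(mask)
        # smooth to break plateau ties, then merge peaks closer than
        # min_separation into a single seed
        smooth = ndimage.gaussian_filter(distance, sigma=1.0)
        peaks = peak_local_max(
            smooth, min_distance=min_separation, labels=mask, exclude_border=False
        )
        peak_mask = np.zeros(mask.shape, dtype=bool)
        peak_mask[tuple(peaks.T)] = True
        peak_mask = morphology.dilation(peak_mask, morphology.disk(min_separation))
        markers, _ = ndimage.label(peak_mask & mask)
        labels = segmentation.watershed(-distance, markers, mask=mask)
    else:
        labels = measure.label(mask)

    records: list[ParticleRecord] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        perimeter = prop.perimeter
        circ = 4.0 * np.pi * prop.area / perimeter**2 if perimeter > 0 else 0.0
        cy, cx = prop.centroid
        records.append(
            ParticleRecord(
                label=int(prop.label),
                centroid=(float(cx), float(cy)),
                area=float(prop.area),
                major_axis=float(prop.axis_major_length * binned_px),
                minor_axis=float(prop.axis_minor_length * binned_px),
                circularity=float(circ),
            )
        )
    return records


@dataclass
class MaskPair:
    """Binary masks of the two channels and their overlap.

    ``reference_mask`` is the (inverted) zero-loss channel, ``query_mask``
    the elemental-map channel; ``overlap_mask`` is their logical AND.
    """

    reference_mask: np.ndarray
    query_mask: np.ndarray

    def __post_init__(self) -> None:
        self.reference_mask = np.asarray(self.reference_mask, bool)
        self.query_mask = np.asarray(self.query_mask, bool)
        if self.reference_mask.shape != self.query_mask.shape:
            raise ValueError("mask shapes differ")

    @property
    def overlap_mask(self) -> np.ndarray:
        return self.reference_mask & self.query_mask


def enhance_small_particle_images(
    zero_loss: FilteredImage | np.ndarray,
    el_map,
    *,
    bin_factor: int = 8,
    sigma_zl: float = 1.0,
    sigma_el: float = 2.0,
    threshold: str | float = "otsu",
    min_area: int = 4,
) -> MaskPair:
    """Enhance and binarize the zero-loss / elemental-map channel pair.

    Both channels are block-binned and Gaussian-blurred (sigmas in
    binned pixels); the zero-loss channel is inverted so particles are
    bright in both, then both are converted to 8 bit and binarized.
    Specks below ``min_area`` binned pixels are removed from both masks.
    """
    zl = zero_loss.pixels if isinstance(zero_loss, FilteredImage) else np.asarray(zero_loss, float)
    el = getattr(el_map, "values", None)
    if el is None:
        el = el_map.pixels if isinstance(el_map, FilteredImage) else np.asarray(el_map, float)
    if zl.shape != el.shape:
        raise ValueError(f"shape mismatch: {zl.shape} vs {el.shape}")

    zl_b = ndimage.gaussian_filter(bin_image(zl, bin_factor), sigma_zl)
    zl_b = zl_b.max() - zl_b  # invert: particles are dark in zero-loss
    el_b = ndimage.gaussian_filter(bin_image(el, bin_factor), sigma_el)

    ref = _binarize(_to_uint8(zl_b), threshold)
    qry = _binarize(_to_uint8(el_b), threshold)
    if min_area > 0:
        ref = morphology.remove_small_objects(ref, max_size=min_area - 1)
        qry = morphology.remove_small_objects(qry, max_size=min_area - 1)
    return MaskPair(reference_mask=ref, query_mask=qry)


def overlap_stats(
    pair: MaskPair,
    truth_mask: np.ndarray | None = None,
    min_overlap_fraction: float = 0.5,
) -> dict:
    """Component and area overlap statistics for a mask pair.

    Reports, for each direction, how many connected components of one
    mask are touched by the other, and the overlapped area fractions.
    With a ground-truth mask, also reports how many truth components are
    *recovered* by the overlap mask.  A truth component counts as
    recovered only if at least ``min_overlap_fraction`` of its area lies
    inside the overlap mask: mere intersection is not detection when a
    near-threshold binarization degenerates into a dense noise mask that
    touches everything by chance.
    """
    ref, qry = pair.reference_mask, pair.query_mask
    overlap = pair.overlap_mask

    def _touched(mask: np.ndarray, other: np.ndarray) -> tuple[int, int]:
        labels = measure.label(mask)
        n = int(labels.max())
        touched = len(np.unique(labels[other & (labels > 0)]))
        return n, touched

    n_ref, ref_touched = _touched(ref, qry)
    n_qry, qry_touched = _touched(qry, ref)
    stats = {
        "n_reference_components": n_ref,
        "n_query_components": n_qry,
        "n_reference_touched": ref_touched,
        "n_query_touched": qry_touched,
        "reference_area_fraction": float(overlap.sum() / ref.sum()) if ref.any() else 0.0,
        "query_area_fraction": float(overlap.sum() / qry.sum()) if qry.any() else 0.0,
    }
    if truth_mask is not None:
        truth = np.asarray(truth_mask, bool)
        labels = measure.label(truth)
        n_truth = int(labels.max())
        detected = 0
        for prop in measure.regionprops(labels):
            blob = labels == prop.label
            frac = overlap[blob].mean()
            if frac >= min_overlap_fraction:
                detected += 1
        stats["n_truth_components"] = n_truth
        stats["n_truth_detected"] = detected
        stats["truth_detection_fraction"] = detected / n_truth if n_truth else 0.0
    return stats
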