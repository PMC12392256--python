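"""Scalar and field quantifications: ice thickness, dose, S/B, spectra.

Ice thickness follows the log-ratio method: with an inelastic mean free
path Lambda (about 400 nm for 300 kV electrons in vitreous ice), the
thickness is t = Lambda * ln(I_unfiltered / I_zero_loss).  Dose
accounting mirrors the acquisition protocol: the per-acquisition total
exposure is the sum of the prepre, pre and core exposures (the pre and
core windows share an exposure time), with the short zero-loss exposure
tracked separately; total dose = dose rate x total exposure, rounded
half-away-from-zero at the precision at which it is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .images import FilteredImage

__all__ = [
    "ThicknessEstimate",
    "DoseRecord",
    "SBRatio",
    "round_half_away",
    "ice_thickness",
    "dose_budget",
    "spectral_dose_budget",
    "combined_dose",
    "signal_to_background",
    "sum_spectrum_window",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (456.5 -> 457), unlike banker's rounding."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class ThicknessEstimate:
    """Log-ratio thickness map with the inputs that produced it."""

    t: np.ndarray  # nm
    mean_free_path: float  # nm
    ratio: np.ndarray  # I_unfiltered / I_zero_loss
    valid: np.ndarray

    @property
    def mean(self) -> float:
        """Mean thickness over valid pixels, nm."""
        if not self.valid.any():
            return float("nan")
        return float(np.mean(self.t[self.valid]))


def ice_thickness(
    unfiltered: FilteredImage | np.ndarray,
    zero_loss: FilteredImage | np.ndarray,
    mean_free_path: float = 400.0,
) -> ThicknessEstimate:
    """Per-pixel ice thickness t = Lambda * ln(I_-ef / I_+ef).

    Pixels where the zero-loss intensity is <= 0 or the ratio is < 1
    (unphysical: filtering cannot add electrons) are flagged invalid.
    """
    if mean_free_path <= 0:
        raise ValueError("mean free path must be > 0")
    i_un = unfiltered.pixels if isinstance(unfiltered, FilteredImage) else np.asarray(unfiltered, float)
    i_zl = zero_loss.pixels if isinstance(zero_loss, FilteredImage) else np.asarray(zero_loss, float)
    if i_un.shape != i_zl.shape:
        raise ValueError(f"shape mismatch: {i_un.shape} vs {i_zl.shape}")
    ratio = np.full(i_un.shape, np.nan)
    ok = i_zl > 0
    ratio[ok] = i_un[ok] / i_zl[ok]
    valid = ok & (ratio >= 1.0)
    t = np.zeros(i_un.shape)
    t[valid] = mean_free_path * np.log(ratio[valid])
    return ThicknessEstimate(t=t, mean_free_path=mean_free_path, ratio=ratio, valid=valid)


@dataclass
class DoseRecord:
    """Dose bookkeeping for one acquisition (one element, one ROI).

    ``total_exposure`` covers the signal windows only (prepre + pre +
    core); the zero-loss exposure and its dose are reported separately.
    ``total_dose`` is rounded half-away-from-zero at ``precision``
    decimals; ``total_dose_exact`` keeps the unrounded product.
    """

    dose_rate: float  # e-/A^2/s
    zero_loss: float  # s
    prepre: float  # s
    pre: float  # s
    core: float  # s
    precision: int = 1

    def __post_init__(self) -> None:
        for name in ("dose_rate", "zero_loss", "prepre", "pre", "core"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_exposure(self) -> float:
        return self.prepre + self.pre + self.core

    @property
    def total_dose_exact(self) -> float:
        return self.dose_rate * self.total_exposure

    @property
    def total_dose(self) -> float:
        return round_half_away(self.total_dose_exact, self.precision)

    @property
    def zero_loss_dose(self) -> float:
        # the zero-loss dose is small; it is always quoted with >= 1 decimal
        return round_half_away(self.dose_rate * self.zero_loss, max(self.precision, 1))


def dose_budget(
    dose_rate: float,
    prepre: float,
    pre: float,
    core: float | None = None,
    zero_loss: float = 0.0,
    precision: int = 1,
) -> DoseRecord:
    """Dose record for one imaging acquisition.

    ``core`` defaults to ``pre`` (the protocol uses the same exposure
    for the pre-edge and core-loss windows), so the total exposure is
    prepre + 2 x pre.
    """
    if core is None:
        core = pre
    return DoseRecord(
        dose_rate=dose_rate,
        zero_loss=zero_loss,
        prepre=prepre,
        pre=pre,
        core=core,
        precision=precision,
    )


def spectral_dose_budget(
    dose_rate: float,
    core_exposures: Sequence[float],
    zero_loss: float = 0.063,
    precision: int = 1,
) -> DoseRecord:
    """Dose record for a spectral session (core-loss exposures only).

    A spectrum session records one short zero-loss spectrum and one
    core-loss spectrum per element; the total exposure is the sum of the
    core-loss exposures of all elements measured in the session.
    """
    total = float(sum(core_exposures))
    return DoseRecord(
        dose_rate=dose_rate,
        zero_loss=zero_loss,
        prepre=0.0,
        pre=0.0,
        core=total,
        precision=precision,
    )


def combined_dose(records: Iterable[DoseRecord], rounded: bool = True) -> float:
    """Summed total dose over several acquisitions (e.g. multi-element)."""
    if rounded:
        return float(sum(r.total_dose for r in records))
    return float(sum(r.total_dose_exact for r in records))


@dataclass
class SBRatio:
    """Signal-to-background ratio of mean intensities in two masks."""

    fg_mean: float
    bg_mean: float

    @property
    def ratio(self) -> float:
        return self.fg_mean / self.bg_mean


def signal_to_background(
    image,
    fg_mask: np.ndarray,
    bg_mask: np.ndarray,
    statistic: str = "mean",
) -> SBRatio:
    """Ratio of foreground to background intensity in two disjoint ROIs.

    ``image`` may be an ElementMap, FilteredImage or plain array; only
    pixels valid in the image's own mask are used.  The statistic is the
    mean by default (median behind the flag).  Raises on empty masks,
    overlapping masks, or a non-positive background level (in which case
    compute the ratio on the raw core-loss image instead).
    """
    pixels = getattr(image, "values", None)
    if pixels is None:
        pixels = getattr(image, "pixels", None)
    if pixels is None:
        pixels = np.asarray(image, dtype=np.float64)
    valid = getattr(image, "valid", None)
    valid = np.ones(pixels.shape, bool) if valid is None else np.asarray(valid, bool)
    fg = np.asarray(fg_mask, bool)
    bg = np.asarray(bg_mask, bool)
    if fg.shape != pixels.shape or bg.shape != pixels.shape:
        raise ValueError("mask shape differs from image shape")
    if np.any(fg & bg):
        raise ValueError("foreground and background masks overlap")
    fg &= valid
    bg &= valid
    if not fg.any() or not bg.any():
        raise ValueError("each mask must contain at least one valid pixel")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    fg_val = float(stat(pixels[fg]))
    bg_val = float(stat(pixels[bg]))
    if bg_val <= 0:
        raise ValueError(
            "background level is <= 0; compute the ratio on the raw core-loss "
            "image rather than a background-subtracted map"
        )
    return SBRatio(fg_mean=fg_val, bg_mean=bg_val)


def sum_spectrum_window(
    intensity: np.ndarray, width: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding box-sum of a 1-D spectrum (raw sum, no normalisation).

    Returns the summed trace and a boolean flag marking samples whose
    window fits entirely inside the spectrum; edge samples are truncated
    raw sums and flagged False.  ``width`` must be odd and no longer
    than the spectrum.
    """
    x = np.asarray(intensity, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    if width > x.size:
        raise ValueError(f"width {width} exceeds spectrum length {x.size}")
    summed = np.convolve(x, np.ones(width), mode="same")
    half = width // 2
    full = np.zeros(x.size, dtype=bool)
    full[half : x.size - half] = True
    return summed, full
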