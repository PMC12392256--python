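"""File formats: TIFF/MRC images with JSON metadata sidecars, spectra, configs.

Images are written as 32-bit float (aligned sums of subpixel-shifted
frames are non-integer).  Acquisition metadata that neither TIFF nor MRC
carries natively (window centre/width, exposure, dose rate) travels in a
JSON sidecar next to the image, ``<image>.json``; an image without a
sidecar loads with unknown metadata and a logged warning.  Spectra are
two-column delimited text (energy eV, intensity counts) with a strictly
increasing energy axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .images import EnergyWindow, FilteredImage, FrameStack
from .mrc import read_mrc, write_mrc

__all__ = [
    "SpectrumTable",
    "read_image",
    "write_image",
    "read_spectrum",
    "write_spectrum",
    "load_config",
    "sidecar_path",
]

logger = logging.getLogger(__name__)

_TIFF_EXT = {".tif", ".tiff"}
_MRC_EXT = {".mrc", ".mrcs", ".map"}


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def _window_to_json(window) -> dict | str | None:
    if isinstance(window, EnergyWindow):
        return {"center": window.center, "width": window.width}
    return window


def _window_from_json(obj):
    if isinstance(obj, dict):
        return EnergyWindow(center=obj["center"], width=obj["width"])
    return obj


def write_image(
    path: str | Path,
    image: FilteredImage | FrameStack | np.ndarray,
    *,
    write_sidecar: bool = True,
) -> Path:
    """Write an image or frame stack as TIFF (.tif/.tiff, multipage for
    stacks) or MRC (.mrc/.mrcs), float32, plus a JSON metadata sidecar."""
    path = Path(path)
    ext = path.suffix.lower()

    meta: dict = {}
    if isinstance(image, FrameStack):
        data = image.as_array()
        meta = {
            "kind": "stack",
            "frame_exposure": image.frame_exposure,
            "window": _window_to_json(image.window),
            "dose_rate": image.dose_rate,
            "pixel_size": image.pixel_size,
        }
    elif isinstance(image, FilteredImage):
        data = image.pixels
        meta = {
            "kind": "image",
            "window": _window_to_json(image.window),
            "exposure": image.exposure,
            "dose_rate": image.dose_rate,
            "pixel_size": image.pixel_size,
        }
    else:
        data = np.asarray(image)
        meta = {"kind": "image"}

    data32 = data.astype(np.float32)
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, data32)
    elif ext in _MRC_EXT:
        write_mrc(path, data32, pixel_size_nm=meta.get("pixel_size", 0.0) or 0.0)
    else:
        raise ValueError(
            f"unknown image extension {ext!r}; supported: "
            f"{sorted(_TIFF_EXT | _MRC_EXT)}"
        )
    if write_sidecar:
        sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> FilteredImage | FrameStack:
    """Read a TIFF or MRC image; a 3-D file becomes a FrameStack.

    Metadata comes from the JSON sidecar when present; otherwise the
    image loads with unknown (zeroed) metadata and a warning is logged.
    """
    path = Path(path)
    ext = path.suffix.lower()
    pixel_size = 0.0
    if ext in _TIFF_EXT:
        data = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif ext in _MRC_EXT:
        data, pixel_size = read_mrc(path)
    else:
        raise ValueError(
            f"unknown image extension {ext!r}; supported: "
            f"{sorted(_TIFF_EXT | _MRC_EXT)}"
        )

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    else:
        logger.warning("%s: no metadata sidecar found; metadata unknown", path)

    window = _window_from_json(meta.get("window"))
    pixel_size = meta.get("pixel_size", pixel_size) or pixel_size

    if data.ndim == 3:
        return FrameStack(
            frames=list(data),
            frame_exposure=meta.get("frame_exposure", 0.0),
            window=window,
            dose_rate=meta.get("dose_rate", 0.0),
            pixel_size=pixel_size,
        )
    return FilteredImage(
        pixels=data,
        window=window,
        exposure=meta.get("exposure", 0.0),
        dose_rate=meta.get("dose_rate", 0.0),
        pixel_size=pixel_size,
    )


@dataclass
class SpectrumTable:
    """A 1-D energy-loss spectrum: strictly increasing energy (eV) and
    intensity (counts) of equal length."""

    energy: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.energy.shape != self.intensity.shape or self.energy.ndim != 1:
            raise ValueError("energy and intensity must be 1-D and equal length")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy axis not increasing")

    def __len__(self) -> int:
        return self.energy.size


def read_spectrum(path: str | Path) -> SpectrumTable:
    """Read a two-column delimited spectrum; a non-numeric header line is
    skipped automatically.  Raises if the energy axis is not strictly
    increasing."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    skip = 0
    if lines:
        first = lines[0].replace(",", " ").split()
        try:
            [float(tok) for tok in first]
        except ValueError:
            skip = 1
    delim = "," if lines and "," in lines[skip] else None
    data = np.loadtxt(path, skiprows=skip, delimiter=delim)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (energy, intensity)")
    return SpectrumTable(energy=data[:, 0], intensity=data[:, 1])


def write_spectrum(path: str | Path, spectrum: SpectrumTable) -> Path:
    path = Path(path)
    header = "energy_eV\tintensity_counts"
    np.savetxt(
        path,
        np.column_stack([spectrum.energy, spectrum.intensity]),
        delimiter="\t",
        header=header,
        comments="",
    )
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML (or flat key: value) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg
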