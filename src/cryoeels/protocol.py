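"""Reference acquisition protocols for cryo-EELS spectra and imaging.

The dose bookkeeping of a cryo-EELS experiment on a 300 kV cold-FEG
instrument with an in-column filter, as published for vitrified silica
and hydroxyapatite (HAp) nanoparticle dispersions.  Spectral sessions
share one short zero-loss spectrum and record one core-loss spectrum
per element; imaging acquisitions take a zero-loss image plus one
prepre-edge, one pre-edge and one core-loss exposure (the pre and core
windows share an exposure time).

``precision`` is the number of decimals at which each session's total
dose is reported (doses under ~100 e-/A^2 are quoted to one decimal,
larger ones to the integer).
"""

from __future__ import annotations

from .quantify import DoseRecord, dose_budget, spectral_dose_budget

__all__ = ["SPECTRUM_SESSIONS", "IMAGING_ROWS", "spectrum_records", "imaging_records"]

# Spectral measurement sessions: elements measured back-to-back on one
# ROI share the dose budget.  dose rates in e-/A^2/s, exposures in s.
SPECTRUM_SESSIONS: list[dict] = [
    {
        "label": "carbon film + vitrified ice (C, O)",
        "dose_rate": 19.3,
        "core_exposures": [10.0, 20.0],
        "zero_loss": 0.063,
        "precision": 0,
    },
    {
        "label": "silicon, 50 nm nanoparticles",
        "dose_rate": 20.3,
        "core_exposures": [2.0],
        "zero_loss": 0.063,
        "precision": 1,
    },
    {
        "label": "silicon 100 nm + streptavidin carbon",
        "dose_rate": 21.8,
        "core_exposures": [1.0, 40.0],
        "zero_loss": 0.063,
        "precision": 0,
    },
    {
        "label": "HAp (P, Ca)",
        "dose_rate": 20.3,
        "core_exposures": [1.0, 3.0],
        "zero_loss": 0.063,
        "precision": 1,
    },
]

# Energy-filtered imaging acquisitions, one row per element/sample.
# pixel sizes in nm, exposures in s, dose rates in e-/A^2/s.
IMAGING_ROWS: list[dict] = [
    {
        "label": "carbon from carbon film",
        "element": "C",
        "magnification": "4k",
        "pixel_size": 1.29,
        "zero_loss": 0.5,
        "prepre": 1.0,
        "pre": 5.0,
        "dose_rate": 0.8,
        "slit_width": 40.0,
        "precision": 1,
    },
    {
        "label": "oxygen from vitrified ice",
        "element": "O",
        "magnification": "4k",
        "pixel_size": 1.29,
        "zero_loss": 0.5,
        "prepre": 4.0,
        "pre": 20.0,
        "dose_rate": 0.8,
        "slit_width": 20.0,
        "precision": 1,
    },
    {
        "label": "silicon from 10 nm nanoparticles",
        "element": "Si",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 1.0,
        "prepre": 6.0,
        "pre": 30.0,
        "dose_rate": 7.6,
        "slit_width": 20.0,
        "precision": 0,
    },
    {
        "label": "silicon from 30 and 50 nm nanoparticles",
        "element": "Si",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 0.5,
        "prepre": 4.0,
        "pre": 20.0,
        "dose_rate": 7.6,
        "slit_width": 20.0,
        "precision": 0,
    },
    {
        "label": "silicon from 100 nm nanoparticles",
        "element": "Si",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 0.5,
        "prepre": 4.0,
        "pre": 20.0,
        "dose_rate": 8.0,
        "slit_width": 20.0,
        "precision": 0,
    },
    {
        "label": "carbon from streptavidin",
        "element": "C",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 0.5,
        "prepre": 4.0,
        "pre": 20.0,
        "dose_rate": 8.0,
        "slit_width": 40.0,
        "precision": 0,
    },
    {
        "label": "phosphorus from HAp",
        "element": "P",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 1.0,
        "prepre": 5.0,
        "pre": 25.0,
        "dose_rate": 8.3,
        "slit_width": 15.0,
        "precision": 0,
    },
    {
        "label": "calcium from HAp",
        "element": "Ca",
        "magnification": "25k",
        "pixel_size": 0.21,
        "zero_loss": 1.0,
        "prepre": 5.0,
        "pre": 25.0,
        "dose_rate": 8.3,
        "slit_width": 15.0,
        "precision": 0,
    },
]


def spectrum_records() -> list[tuple[str, DoseRecord]]:
    return [
        (
            row["label"],
            spectral_dose_budget(
                row["dose_rate"],
                row["core_exposures"],
                zero_loss=row["zero_loss"],
                precision=row["precision"],
            ),
        )
        for row in SPECTRUM_SESSIONS
    ]


def imaging_records() -> list[tuple[str, DoseRecord]]:
    return [
        (
            row["label"],
            dose_budget(
                row["dose_rate"],
                row["prepre"],
                row["pre"],
                zero_loss=row["zero_loss"],
                precision=row["precision"],
            ),
        )
        for row in IMAGING_ROWS
    ]
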