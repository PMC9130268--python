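"""Spectral band definitions for the 7-band multispectral endoscope.

The light source provides seven wavelength bands from near-UV to red.
Band order is fixed (increasing wavelength) and used as the page order of
multi-page TIFF cohort files.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandSpec", "DEFAULT_BANDS", "band_index"]


@dataclass(frozen=True)
class BandSpec:
    """One spectral band of the imaging device."""

    centre_wavelength_nm: float
    name: str


#: Centre wavelengths of the multispectral endoscope, in acquisition order.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(396.0, "UV"),
    BandSpec(438.0, "Blue"),
    BandSpec(475.0, "Cyan"),
    BandSpec(512.0, "Teal"),
    BandSpec(542.0, "Green"),
    BandSpec(575.0, "Yellow"),
    BandSpec(628.0, "Red"),
)


def validate_bands(bands: tuple[BandSpec, ...] | list[BandSpec]) -> None:
    """Check the 7-band contract: exactly seven bands, strictly increasing."""
    if len(bands) != 7:
        raise ValueError(f"expected exactly 7 bands, got {len(bands)}")
    wl = [b.centre_wavelength_nm for b in bands]
    if any(w2 <= w1 for w1, w2 in zip(wl, wl[1:])):
        raise ValueError("band wavelengths must be strictly increasing")


def band_index(bands, name: str) -> int:
    """Index of the band called *name* (e.g. ``'Red'``); raises KeyError."""
    for i, b in enumerate(bands):
        if b.name == name:
            return i
    raise KeyError(f"no band named {name!r}")
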