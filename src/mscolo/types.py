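"""Shared container types: multispectral image cubes and pixel masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandSpec, DEFAULT_BANDS

__all__ = ["MultiSpectralImage", "PixelMask", "MscoloError", "ParameterError",
           "ConfigurationError", "FormatError", "NormalizationError"]


class MscoloError(Exception):
    """Base class for package errors."""


class ParameterError(MscoloError, ValueError):
    """Invalid numeric parameter (shapes, ranges, kernel sizes...)."""


class ConfigurationError(MscoloError, ValueError):
    """Inconsistent configuration (missing bands, unknown options...)."""


class FormatError(MscoloError, ValueError):
    """On-disk cohort data violates the expected layout."""


class NormalizationError(MscoloError, ValueError):
    """Per-band normalization impossible (all-zero band)."""


@dataclass
class MultiSpectralImage:
    """A height x width x n_bands intensity cube I(x, y, lambda).

    Intensities are floats in [0, 1]; saturation is represented by clipping
    at 1.0.  ``bands`` carries the centre wavelength and colour name of each
    spectral plane, in plane order.
    """

    data: np.ndarray
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("image data must be (height, width, n_bands)")
        if self.data.shape[2] != len(self.bands):
            raise ParameterError(
                f"{self.data.shape[2]} planes but {len(self.bands)} band specs")
        if not np.isfinite(self.data).all():
            raise ParameterError("image intensities must be finite")
        if (self.data < 0).any():
            raise ParameterError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (height, width)."""
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return the 2-D plane of the band called *name*."""
        from .bands import band_index

        return self.data[:, :, band_index(self.bands, name)]

    def copy(self) -> "MultiSpectralImage":
        return MultiSpectralImage(self.data.copy(), self.bands)


@dataclass
class PixelMask:
    """A boolean spatial mask with a provenance tag.

    ``valid`` follows the convention of the stage that produced it: for
    exclusion masks True means "usable pixel", for label masks True means
    "lesion pixel".
    """

    valid: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim != 2:
            raise ParameterError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def __and__(self, other: "PixelMask") -> "PixelMask":
        if self.shape != other.shape:
            raise ParameterError("mask shapes differ")
        return PixelMask(self.valid & other.valid,
                         provenance=f"{self.provenance}&{other.provenance}")

    def fraction_excluded(self) -> float:
        return float(1.0 - self.valid.mean())
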