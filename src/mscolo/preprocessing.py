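"""Pre-processing chain for multispectral colonoscopy cubes.

The chain runs, in order:

1. specular/dark exclusion — pixels whose red- or yellow-band intensity is
   below 5% of that band's image maximum are excluded, together with all
   pixels within 5 px of them;
2. Gaussian filtering (7x7 kernel, sigma 1 px) so the MNF does not carry
   single-band noise artefacts into other bands;
3. lesion-margin exclusion — 5 px on both sides of the expert-drawn lesion
   boundary are removed from training/testing, since the drawn margin is
   uncertain;
4. per-band normalization I_norm = I / max_{x,y} I, tile-wise minimum noise
   fraction (MNF) denoising with a regression-based noise model, and
   de-normalization with the saved maxima;

followed by a second Gaussian filter (11x11, sigma 2 px).

Noise inside each MNF tile is estimated by regressing every band on the
remaining bands (support-vector regression by default; multilinear
regression as in the classical MNF, or a spatial shift-difference, are
selectable) and taking the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import (ConfigurationError, MultiSpectralImage, NormalizationError,
                    ParameterError, PixelMask)
from .bands import band_index

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationRecord", "MNFConfig", "PreprocessConfig", "PreprocessResult",
    "exclude_specular_and_dark", "gaussian_filter_stack", "exclude_lesion_margin",
    "normalize", "denormalize", "estimate_noise", "mnf_denoise", "preprocess",
]


@dataclass
class NormalizationRecord:
    """Per-band maxima saved by :func:`normalize` for de-normalization."""

    per_band_max: np.ndarray

    def __post_init__(self) -> None:
        self.per_band_max = np.asarray(self.per_band_max, dtype=float)
        if self.per_band_max.ndim != 1 or (self.per_band_max <= 0).any():
            raise NormalizationError("per-band maxima must be a strictly positive vector")


@dataclass
class MNFConfig:
    """Minimum-noise-fraction configuration.

    ``tile_size`` is the sub-image edge length in pixels; ``n_drop`` trailing
    (lowest signal-to-noise) components are zeroed before the inverse
    transform.  ``noise_estimator`` selects how per-pixel noise is estimated
    inside a tile.
    """

    tile_size: int = 20
    n_drop: int = 3
    noise_estimator: str = "svr"  # svr | multilinear | shift_difference
    svr_c: float = 1.0
    svr_epsilon: float = 0.01
    svr_gamma: str | float = "scale"

    def validate(self, n_bands: int) -> None:
        if self.tile_size < 2:
            raise ParameterError("tile_size must be >= 2")
        if not 0 <= self.n_drop < n_bands:
            raise ParameterError("n_drop must satisfy 0 <= n_drop < n_bands")
        if self.noise_estimator not in ("svr", "multilinear", "shift_difference"):
            raise ConfigurationError(
                f"unknown noise estimator {self.noise_estimator!r}")


@dataclass
class PreprocessConfig:
    """Parameters of the full pre-processing chain."""

    dark_threshold_fraction: float = 0.05
    dark_exclusion_radius_px: float = 5.0
    exclusion_metric: str = "euclidean"  # or "chebyshev"
    first_filter: tuple[int, float] = (7, 1.0)
    margin_px: float = 5.0
    mnf: MNFConfig = field(default_factory=MNFConfig)
    second_filter: tuple[int, float] = (11, 2.0)


@dataclass
class StageLog:
    stage: str
    excluded_fraction: float | None = None
    note: str = ""


@dataclass
class PreprocessResult:
    image: MultiSpectralImage
    valid: PixelMask
    norm: NormalizationRecord
    stages: list[StageLog]


# ---------------------------------------------------------------------------
# stage 1: specular / dark exclusion


def exclude_specular_and_dark(image: MultiSpectralImage,
                              threshold_fraction: float = 0.05,
                              exclusion_radius_px: float = 5.0,
                              metric: str = "euclidean") -> PixelMask:
    """Exclude too-dark pixels (specular artefact surroundings included).

    A pixel is invalid iff its red-band OR yellow-band intensity falls below
    ``threshold_fraction`` of that band's per-image maximum; every pixel
    within ``exclusion_radius_px`` of an invalid pixel is also excluded.
    The neighbourhood is a Euclidean disc by default (``metric='chebyshev'``
    gives a square).
    """
    try:
        red = image.band("Red")
        yellow = image.band("Yellow")
    except KeyError as exc:
        raise ConfigurationError("image lacks a Red or Yellow band") from exc
    dark = (red < threshold_fraction * red.max()) | \
        (yellow < threshold_fraction * yellow.max())
    if dark.any():
        if metric == "euclidean":
            dist = ndimage.distance_transform_edt(~dark)
        elif metric == "chebyshev":
            dist = ndimage.distance_transform_cdt(~dark, metric="chessboard")
        else:
            raise ConfigurationError(f"unknown exclusion metric {metric!r}")
        invalid = dist <= exclusion_radius_px
    else:
        invalid = dark
    return PixelMask(~invalid, provenance="specular_dark")


# ---------------------------------------------------------------------------
# stage 2/7: Gaussian filtering


def _gaussian_kernel(size_px: int, sigma_px: float) -> np.ndarray:
    """Truncated, normalized 2-D Gaussian kernel of odd edge length."""
    if size_px % 2 == 0 or size_px < 1:
        raise ParameterError("kernel size must be odd and positive")
    if sigma_px <= 0:
        raise ParameterError("sigma must be positive")
    half = size_px // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kernel = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma_px ** 2))
    return kernel / kernel.sum()


def gaussian_filter_stack(image: MultiSpectralImage, size_px: int,
                          sigma_px: float) -> MultiSpectralImage:
    """Per-band convolution with a truncated normalized Gaussian kernel.

    Borders use reflect padding.
    """
    kernel = _gaussian_kernel(size_px, sigma_px)
    out = np.empty_like(image.data)
    for b in range(image.n_bands):
        out[:, :, b] = ndimage.convolve(image.data[:, :, b], kernel, mode="reflect")
    return MultiSpectralImage(np.clip(out, 0.0, None), image.bands)


# ---------------------------------------------------------------------------
# stage 3: lesion margin exclusion


def exclude_lesion_margin(label_mask: PixelMask, margin_px: float = 5.0) -> PixelMask:
    """Exclude pixels within ``margin_px`` of the lesion boundary (both sides).

    The expert-drawn margin carries a definite localisation error, so pixels
    near it are dropped from training and testing.  An empty (or full)
    lesion mask has no boundary and nothing is excluded.
    """
    lesion = label_mask.valid
    if not lesion.any() or lesion.all():
        return PixelMask(np.ones_like(lesion, dtype=bool), provenance="margin")
    dist_to_lesion = ndimage.distance_transform_edt(~lesion)
    dist_to_healthy = ndimage.distance_transform_edt(lesion)
    # exactly one of the two distances is nonzero at any pixel
    dist_to_boundary = np.where(lesion, dist_to_healthy, dist_to_lesion)
    return PixelMask(dist_to_boundary > margin_px, provenance="margin")


# ---------------------------------------------------------------------------
# stage 4a/4c: normalization


def normalize(image: MultiSpectralImage) -> tuple[MultiSpectralImage, NormalizationRecord]:
    """Divide every band by its per-image maximum (saved for de-normalization)."""
    maxima = image.data.reshape(-1, image.n_bands).max(axis=0)
    if (maxima <= 0).any():
        raise NormalizationError("cannot normalize an all-zero band")
    record = NormalizationRecord(maxima)
    return MultiSpectralImage(image.data / maxima[None, None, :], image.bands), record


def denormalize(image_norm: MultiSpectralImage,
                record: NormalizationRecord) -> MultiSpectralImage:
    """Invert :func:`normalize` using the saved per-band maxima."""
    if record.per_band_max.shape[0] != image_norm.n_bands:
        raise ParameterError("normalization record does not match band count")
    return MultiSpectralImage(
        image_norm.data * record.per_band_max[None, None, :], image_norm.bands)


# ---------------------------------------------------------------------------
# stage 4b: MNF denoising


def _shift_difference_noise(tile: np.ndarray) -> np.ndarray:
    """Classic MNF noise proxy: horizontal neighbour difference / sqrt(2)."""
    shifted = np.concatenate([tile[:, :1, :], tile[:, :-1, :]], axis=1)
    return (tile - shifted) / np.sqrt(2.0)


def estimate_noise(tile: np.ndarray, config: MNFConfig | None = None) -> np.ndarray:
    """Per-pixel noise estimate for a (height, width, n_bands) tile.

    Each band is predicted from the remaining bands with the configured
    regressor; the noise estimate is observed minus predicted.  A tile whose
    bands are (near-)constant cannot support the regression and falls back
    to the shift-difference estimator with a logged warning.
    """
    config = config or MNFConfig()
    tile = np.asarray(tile, dtype=float)
    if tile.ndim != 3:
        raise ParameterError("tile must be (height, width, n_bands)")
    h, w, n_bands = tile.shape
    if config.noise_estimator == "shift_difference":
        return _shift_difference_noise(tile)
    flat = tile.reshape(-1, n_bands)
    if np.ptp(flat, axis=0).max() < 1e-12:
        logger.warning("degenerate (constant) tile: falling back to shift-difference noise")
        return _shift_difference_noise(tile)
    noise = np.empty_like(flat)
    for b in range(n_bands):
        others = np.delete(flat, b, axis=1)
        target = flat[:, b]
        if config.noise_estimator == "multilinear":
            design = np.column_stack([others, np.ones(len(others))])
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            pred = design @ coef
        else:  # svr
            from sklearn.svm import SVR

            reg = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon,
                      gamma=config.svr_gamma)
            reg.fit(others, target)
            pred = reg.predict(others)
        noise[:, b] = target - pred
    return noise.reshape(h, w, n_bands)


def _tile_slices(size: int, tile: int, min_pixels_other: int, n_bands: int):
    """1-D tile boundaries; a trailing sliver too small to support the
    covariance estimates is merged into the previous tile."""
    edges = list(range(0, size, tile)) + [size]
    if len(edges) > 2 and (edges[-1] - edges[-2]) * min_pixels_other < n_bands:
        del edges[-2]
    return [(a, b) for a, b in zip(edges[:-1], edges[1:])]


def mnf_denoise(image_norm: MultiSpectralImage, valid: PixelMask | None = None,
                config: MNFConfig | None = None) -> MultiSpectralImage:
    """Tile-wise minimum-noise-fraction denoising.

    Per tile: estimate the noise covariance from regression residuals,
    whiten the data by it, eigendecompose the whitened covariance (ordering
    components by signal-to-noise), zero the ``n_drop`` trailing components
    and invert the transform.  With ``n_drop=0`` the transform is an
    identity up to numerical tolerance.
    """
    config = config or MNFConfig()
    n_bands = image_norm.n_bands
    config.validate(n_bands)
    data = image_norm.data
    h, w, _ = data.shape
    if valid is not None and valid.shape != (h, w):
        raise ParameterError("valid mask shape mismatch")
    out = np.empty_like(data)
    row_slices = _tile_slices(h, config.tile_size, w, n_bands)
    col_slices = _tile_slices(w, config.tile_size, h, n_bands)
    for r0, r1 in row_slices:
        for c0, c1 in col_slices:
            tile = data[r0:r1, c0:c1, :]
            vmask = (valid.valid[r0:r1, c0:c1].ravel()
                     if valid is not None else np.ones((r1 - r0) * (c1 - c0), bool))
            out[r0:r1, c0:c1, :] = _mnf_tile(tile, vmask, config)
    return MultiSpectralImage(np.clip(out, 0.0, None), image_norm.bands)


def _mnf_tile(tile: np.ndarray, vmask: np.ndarray, config: MNFConfig) -> np.ndarray:
    h, w, n_bands = tile.shape
    flat = tile.reshape(-1, n_bands)
    if flat.shape[0] < n_bands + 2:
        logger.warning("MNF tile with %d pixels is too small; passed through", flat.shape[0])
        return tile
    if vmask.sum() < n_bands + 2:
        vmask = np.ones(len(flat), dtype=bool)
    noise = estimate_noise(tile, config).reshape(-1, n_bands)

    sigma_n = np.cov(noise[vmask], rowvar=False)
    sigma_n = np.atleast_2d(sigma_n)
    # regularize a singular noise covariance (logged)
    eps = 1e-10 * max(np.trace(sigma_n) / n_bands, 1e-12)
    d, u = np.linalg.eigh(sigma_n)
    if d.min() <= eps:
        logger.warning("singular noise covariance in MNF tile; regularizing")
        sigma_n = sigma_n + np.eye(n_bands) * (eps - min(d.min(), 0.0) + eps)
        d, u = np.linalg.eigh(sigma_n)
    whiten = u @ np.diag(1.0 / np.sqrt(d))
    unwhiten = np.diag(np.sqrt(d)) @ u.T

    mean = flat[vmask].mean(axis=0)
    centred = flat - mean
    y = centred @ whiten
    sigma_y = np.atleast_2d(np.cov(y[vmask], rowvar=False))
    lam, v = np.linalg.eigh(sigma_y)
    order = np.argsort(lam)[::-1]  # descending signal-to-noise
    v = v[:, order]
    z = y @ v
    if config.n_drop > 0:
        z[:, n_bands - config.n_drop:] = 0.0
    recon = (z @ v.T) @ unwhiten + mean
    return recon.reshape(h, w, n_bands)


# ---------------------------------------------------------------------------
# full chain


def preprocess(image: MultiSpectralImage, label_mask: PixelMask,
               config: PreprocessConfig | None = None) -> PreprocessResult:
    """Run the full pre-processing chain on one animal.

    Returns the processed image, the combined validity mask (specular/dark
    AND lesion-margin exclusions) and the normalization record, along with
    an audit log of the stages in execution order.
    """
    config = config or PreprocessConfig()
    stages: list[StageLog] = []

    dark_mask = exclude_specular_and_dark(
        image, config.dark_threshold_fraction, config.dark_exclusion_radius_px,
        config.exclusion_metric)
    stages.append(StageLog("exclude_specular_and_dark",
                           excluded_fraction=dark_mask.fraction_excluded()))

    size1, sigma1 = config.first_filter
    smoothed = gaussian_filter_stack(image, size1, sigma1)
    stages.append(StageLog("gaussian_filter_stack",
                           note=f"size={size1}, sigma={sigma1}"))

    margin_mask = exclude_lesion_margin(label_mask, config.margin_px)
    stages.append(StageLog("exclude_lesion_margin",
                           excluded_fraction=margin_mask.fraction_excluded()))

    normed, record = normalize(smoothed)
    stages.append(StageLog("normalize"))

    denoised = mnf_denoise(normed, dark_mask, config.mnf)
    stages.append(StageLog("mnf_denoise",
                           note=f"tile={config.mnf.tile_size}, n_drop={config.mnf.n_drop}, "
                                f"estimator={config.mnf.noise_estimator}"))

    restored = denormalize(denoised, record)
    stages.append(StageLog("denormalize"))

    size2, sigma2 = config.second_filter
    final = gaussian_filter_stack(restored, size2, sigma2)
    stages.append(StageLog("gaussian_filter_stack",
                           note=f"size={size2}, sigma={sigma2}"))

    combined = dark_mask & margin_mask
    combined.provenance = "specular_dark&margin"
    return PreprocessResult(image=final, valid=combined, norm=record, stages=stages)
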