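"""Synthetic multispectral endoscopy cohorts with known ground truth.

The in-vivo images this pipeline was designed for are not publicly
deposited, so every downstream stage is exercised on a simulator that
emulates the salient physics of multispectral colonoscopy frames:

* band-dependent diffuse reflectance (lowest in the UV/blue bands; healthy
  mucosa relatively brighter than neoplastic tissue in yellow/red compared
  to green),
* neoplastic lesions as unions of discs with smoothly perturbed boundaries,
* band-correlated low-pass texture, separately parameterised for lesion and
  healthy tissue so that spatial features can carry class signal,
* near-saturated specular highlight discs,
* radial vignetting producing dark corners,
* optional per-band multiplicative gain jitter, and
* i.i.d. additive sensor noise, with saturation modelled by clipping to 1.

Intensities are floats in [0, 1].  Cohorts round-trip to disk as multi-page
TIFF (one page per band, in band order), 8-bit PNG lesion masks
(0 = healthy, 255 = lesion) and a YAML manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .bands import BandSpec, DEFAULT_BANDS, validate_bands
from .types import FormatError, MultiSpectralImage, ParameterError, PixelMask

__all__ = [
    "CohortParams", "AnimalSample", "generate_cohort",
    "write_cohort", "read_cohort",
    "desk_scale_params", "strong_contrast_params", "zero_contrast_params",
    "texture_contrast_params",
]

# Qualitative reflectance profiles: UV/blue lowest, green slightly below
# yellow/red for healthy mucosa; the lesion loses brightness in yellow/red
# relative to green, which is the main spectral class contrast.
_HEALTHY_REFLECTANCE = (0.15, 0.20, 0.35, 0.45, 0.55, 0.70, 0.72)
_LESION_REFLECTANCE = (0.17, 0.22, 0.38, 0.48, 0.58, 0.58, 0.56)


@dataclass
class CohortParams:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults follow the acquisition geometry (520 x 496 px crops, 25
    animals, each with at least one lesion, split 14/11 between spontaneous
    and inflammation-driven tumour models).  Absolute reflectance levels are
    not constrained by any measurement; they only honour the qualitative
    band ordering described above.
    """

    n_animals: int = 25
    image_shape: tuple[int, int] = (520, 496)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (30.0, 80.0)
    band_reflectance_healthy: tuple[float, ...] = _HEALTHY_REFLECTANCE
    band_reflectance_lesion: tuple[float, ...] = _LESION_REFLECTANCE
    texture_amplitude: float = 0.03
    texture_scale_px: float = 8.0
    lesion_texture_amplitude: float | None = None  # None -> same as healthy
    lesion_texture_scale_px: float | None = None
    specular_spot_count: int = 2
    specular_radius_px: float = 5.0
    vignette_strength: float = 0.999
    vignette_exponent: float = 1.8
    band_gain_jitter: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ParameterError("image dimensions must be positive")
        validate_bands(self.bands)
        lo, hi = self.lesion_count_range
        if lo < 1 or hi < lo:
            raise ParameterError("lesion_count_range must satisfy 1 <= min <= max")
        rlo, rhi = self.lesion_radius_range
        if rlo <= 0 or rhi < rlo:
            raise ParameterError("lesion_radius_range must satisfy 0 < min <= max")
        if 2 * rhi >= min(h, w):
            raise ParameterError("maximal lesion radius does not fit in the image")
        for vec in (self.band_reflectance_healthy, self.band_reflectance_lesion):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (len(self.bands),):
                raise ParameterError("reflectance vectors must have one entry per band")
            if (arr <= 0).any() or (arr > 1).any():
                raise ParameterError("reflectance values must lie in (0, 1]")
        if not 0 <= self.vignette_strength < 1:
            raise ParameterError("vignette_strength must be in [0, 1)")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ParameterError("noise_sd and texture_amplitude must be >= 0")


@dataclass
class AnimalSample:
    """One animal: a multispectral cube, its expert lesion mask and metadata."""

    image: MultiSpectralImage
    lesion_mask: PixelMask
    animal_id: str
    model_group: str  # "spontaneous" | "inflammation"

    def __post_init__(self) -> None:
        if self.image.shape != self.lesion_mask.shape:
            raise ParameterError("mask shape must equal image spatial shape")
        if not self.lesion_mask.valid.any():
            raise ParameterError("each animal must carry at least one lesion")


def _perturbed_disc(shape, centre, radius, rng) -> np.ndarray:
    """Disc with a smooth low-order boundary perturbation r(theta)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - centre[0]
    dx = xx - centre[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = np.full_like(theta, float(radius))
    for k in range(2, 5):
        amp = rng.normal(0.0, 0.06) * radius
        phase = rng.uniform(0, 2 * np.pi)
        r_theta = r_theta + amp * np.cos(k * theta + phase)
    r_theta = np.clip(r_theta, 0.3 * radius, 1.7 * radius)
    return rho <= r_theta


def _lowpass_field(shape, scale_px, rng) -> np.ndarray:
    """Unit-variance low-pass Gaussian random field (correlation ~scale_px)."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale_px,
                                    mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


def _generate_animal(params: CohortParams, rng, animal_id, model_group) -> AnimalSample:
    h, w = params.image_shape
    n_bands = len(params.bands)
    healthy = np.asarray(params.band_reflectance_healthy, dtype=float)
    lesion_ref = np.asarray(params.band_reflectance_lesion, dtype=float)

    # lesion mask: union of perturbed discs, fully inside the frame
    mask = np.zeros((h, w), dtype=bool)
    n_lesions = int(rng.integers(params.lesion_count_range[0],
                                 params.lesion_count_range[1] + 1))
    for _ in range(n_lesions):
        radius = rng.uniform(*params.lesion_radius_range)
        margin = int(np.ceil(radius)) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        mask |= _perturbed_disc((h, w), (cy, cx), radius, rng)

    m = mask.astype(float)
    base = healthy[None, None, :] * (1.0 - m[:, :, None]) + \
        lesion_ref[None, None, :] * m[:, :, None]

    # band-correlated texture: one spatial field per tissue class, scaled per
    # band by the healthy reflectance profile so bands co-vary
    lesion_amp = (params.texture_amplitude
                  if params.lesion_texture_amplitude is None
                  else params.lesion_texture_amplitude)
    lesion_scale = (params.texture_scale_px
                    if params.lesion_texture_scale_px is None
                    else params.lesion_texture_scale_px)
    tex = np.zeros((h, w))
    same_texture = (lesion_amp == params.texture_amplitude
                    and lesion_scale == params.texture_scale_px)
    if same_texture:
        # identical texture statistics: one continuous field, otherwise the
        # seam between two independent realizations would mark the boundary
        # even when the classes are meant to be indistinguishable
        if params.texture_amplitude > 0:
            tex = params.texture_amplitude * \
                _lowpass_field((h, w), params.texture_scale_px, rng)
    else:
        if params.texture_amplitude > 0:
            tex += params.texture_amplitude * \
                _lowpass_field((h, w), params.texture_scale_px, rng) * (1.0 - m)
        if lesion_amp > 0:
            tex += lesion_amp * _lowpass_field((h, w), lesion_scale, rng) * m
    band_weight = healthy / healthy.max()
    cube = base + tex[:, :, None] * band_weight[None, None, :]

    # radial vignetting (dark corners)
    if params.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        r_max = np.hypot((h - 1) / 2.0, (w - 1) / 2.0)
        falloff = 1.0 - params.vignette_strength * (r / r_max) ** params.vignette_exponent
        cube *= falloff[:, :, None]

    if params.band_gain_jitter > 0:
        gains = 1.0 + params.band_gain_jitter * rng.standard_normal(n_bands)
        cube *= np.clip(gains, 0.1, None)[None, None, :]

    if params.noise_sd > 0:
        cube = cube + rng.normal(0.0, params.noise_sd, size=cube.shape)

    # specular highlights: saturated discs painted over everything
    for _ in range(params.specular_spot_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        yy, xx = np.mgrid[0:h, 0:w]
        spot = np.hypot(yy - cy, xx - cx) <= params.specular_radius_px
        cube[spot, :] = 1.0

    cube = np.clip(cube, 0.0, 1.0)
    return AnimalSample(
        image=MultiSpectralImage(cube, params.bands),
        lesion_mask=PixelMask(mask, provenance="label"),
        animal_id=animal_id,
        model_group=model_group,
    )


def generate_cohort(params: CohortParams) -> list[AnimalSample]:
    """Generate a deterministic cohort of ``params.n_animals`` animals.

    The tumour-model split emulates the 14/11 spontaneous-vs-inflammation
    composition of the in-vivo study, proportionally rescaled for other
    cohort sizes.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n_spont = int(round(params.n_animals * 14 / 25))
    n_spont = min(max(n_spont, 1 if params.n_animals > 1 else 0), params.n_animals)
    samples = []
    for i in range(params.n_animals):
        group = "spontaneous" if i < n_spont else "inflammation"
        samples.append(_generate_animal(params, rng, f"mouse{i:03d}", group))
    return samples


# ---------------------------------------------------------------------------
# named study conditions at desk scale
#
# The benchmark cohorts used by the analysis scripts and the validation
# suite: 64x64 frames (lesion geometry rescaled accordingly) so a full
# leave-one-animal-out run stays cheap on one CPU.


def desk_scale_params(n_animals: int = 10, seed: int = 0, **overrides) -> CohortParams:
    """Baseline 64x64 cohort with the default spectral class contrast."""
    base = dict(
        n_animals=n_animals, image_shape=(64, 64),
        lesion_count_range=(1, 2), lesion_radius_range=(8.0, 12.0),
        specular_spot_count=1, specular_radius_px=3.0,
        # corner-only vignetting: a steeper profile than the full-frame
        # default so the small field of view keeps its mid-field intensity
        vignette_strength=0.6, vignette_exponent=3.0,
        noise_sd=0.01, seed=seed)
    base.update(overrides)
    return CohortParams(**base)


def strong_contrast_params(n_animals: int = 10, seed: int = 0) -> CohortParams:
    """Strong spectral lesion contrast, low noise: classifiers should
    recover the lesions nearly perfectly under leave-one-animal-out."""
    return desk_scale_params(
        n_animals=n_animals, seed=seed,
        band_reflectance_lesion=(0.25, 0.30, 0.50, 0.65, 0.75, 0.45, 0.40),
        noise_sd=0.005, texture_amplitude=0.01)


def zero_contrast_params(n_animals: int = 10, seed: int = 0) -> CohortParams:
    """Lesion and healthy tissue share reflectance and texture statistics:
    any classifier's mean MCC should sit at chance level.

    Vignetting is disabled here: lesions never touch the frame border, so a
    radial intensity falloff would hand classifiers a positional proxy even
    when tissue contrast is exactly zero."""
    return desk_scale_params(
        n_animals=n_animals, seed=seed,
        band_reflectance_lesion=_HEALTHY_REFLECTANCE,
        vignette_strength=0.0,
        noise_sd=0.01)


def texture_contrast_params(n_animals: int = 8, seed: int = 0) -> CohortParams:
    """Lesions differ from healthy tissue chiefly in texture: per-band mean
    reflectance is matched and only the texture field (amplitude and
    correlation length) separates the classes, so the intensity-only
    feature arm has little to work with."""
    return desk_scale_params(
        n_animals=n_animals, seed=seed,
        band_reflectance_lesion=_HEALTHY_REFLECTANCE,
        texture_amplitude=0.05, texture_scale_px=10.0,
        lesion_texture_amplitude=0.15, lesion_texture_scale_px=4.0,
        noise_sd=0.003)


# ---------------------------------------------------------------------------
# disk round trip

MANIFEST_NAME = "cohort.yaml"


def write_cohort(samples: list[AnimalSample], directory) -> Path:
    """Write a cohort to *directory*; returns the manifest path.

    Layout: ``<animal_id>_image.tif`` (multi-page, one page per band in band
    order), ``<animal_id>_mask.png`` (0 = healthy, 255 = lesion) and a YAML
    manifest recording ids, model groups and band wavelengths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not samples:
        raise ParameterError("cannot write an empty cohort")
    bands = samples[0].image.bands
    entries = []
    for s in samples:
        img_name = f"{s.animal_id}_image.tif"
        mask_name = f"{s.animal_id}_mask.png"
        # float64 pages: stage-wise CLI runs must reproduce the in-memory
        # pipeline exactly
        pages = np.ascontiguousarray(np.moveaxis(s.image.data, 2, 0))
        tifffile.imwrite(directory / img_name, pages)
        iio.imwrite(directory / mask_name,
                    (s.lesion_mask.valid.astype(np.uint8) * 255))
        entries.append({"animal_id": s.animal_id,
                        "model_group": s.model_group,
                        "image": img_name,
                        "mask": mask_name})
    manifest = {
        "bands": [{"centre_wavelength_nm": float(b.centre_wavelength_nm),
                   "name": b.name} for b in bands],
        "animals": entries,
    }
    path = directory / MANIFEST_NAME
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_cohort(directory) -> list[AnimalSample]:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    path = directory / MANIFEST_NAME
    if not path.exists():
        raise FormatError(f"no manifest at {path}")
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    band_entries = manifest.get("bands", [])
    if len(band_entries) != 7:
        raise FormatError(f"manifest lists {len(band_entries)} bands, expected 7")
    bands = tuple(BandSpec(float(b["centre_wavelength_nm"]), str(b["name"]))
                  for b in band_entries)
    samples = []
    for entry in manifest["animals"]:
        pages = tifffile.imread(directory / entry["image"])
        if pages.ndim != 3 or pages.shape[0] != len(bands):
            raise FormatError(
                f"{entry['image']}: expected {len(bands)} pages, got shape {pages.shape}")
        cube = np.moveaxis(pages, 0, 2).astype(float)
        mask_arr = np.asarray(iio.imread(directory / entry["mask"]))
        if mask_arr.ndim != 2 or mask_arr.shape != cube.shape[:2]:
            raise FormatError(
                f"{entry['mask']}: mask shape {mask_arr.shape} does not match "
                f"image spatial shape {cube.shape[:2]}")
        samples.append(AnimalSample(
            image=MultiSpectralImage(cube, bands),
            lesion_mask=PixelMask(mask_arr > 127, provenance="label"),
            animal_id=str(entry["animal_id"]),
            model_group=str(entry["model_group"]),
        ))
    return samples
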