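"""Pre-processing chain: exclusions, filtering, normalization, MNF."""

import numpy as np
import pytest

from mscolo.bands import DEFAULT_BANDS
from mscolo.preprocessing import (MNFConfig, PreprocessConfig,
                                  exclude_lesion_margin,
                                  exclude_specular_and_dark,
                                  gaussian_filter_stack, _gaussian_kernel,
                                  normalize, denormalize, estimate_noise,
                                  mnf_denoise, preprocess)
from mscolo.types import (ConfigurationError, MultiSpectralImage,
                          NormalizationError, ParameterError, PixelMask)
from mscolo import generate_cohort, CohortParams

from conftest import tiny_params


def _cube(data):
    return MultiSpectralImage(data, DEFAULT_BANDS)


# ---------------------------------------------------------------------------
# specular / dark exclusion


def test_uniform_bright_image_keeps_all_pixels(flat_image):
    mask = exclude_specular_and_dark(flat_image)
    assert mask.valid.all()


def test_dark_pixel_excludes_euclidean_disc():
    """A single dark red-band pixel at the centre of a 21x21 frame excludes
    exactly the pixels within Euclidean distance 5, by brute force."""
    data = np.full((21, 21, 7), 0.8)
    data[10, 10, 6] = 0.0  # red band dark
    mask = exclude_specular_and_dark(_cube(data), exclusion_radius_px=5)
    expected = np.ones((21, 21), dtype=bool)
    for r in range(21):
        for c in range(21):
            if (r - 10) ** 2 + (c - 10) ** 2 <= 25:
                expected[r, c] = False
    assert np.array_equal(mask.valid, expected)


def test_dark_yellow_band_also_excludes():
    data = np.full((15, 15, 7), 0.8)
    data[3, 3, 5] = 0.0  # yellow
    mask = exclude_specular_and_dark(_cube(data), exclusion_radius_px=0)
    assert not mask.valid[3, 3]
    assert mask.valid.sum() == 15 * 15 - 1


def test_threshold_is_relative_to_band_maximum():
    data = np.full((10, 10, 7), 0.5)
    data[0, 0, :] = 1.0          # raises the per-band maximum
    data[5, 5, 6] = 0.04         # below 5% of 1.0
    mask = exclude_specular_and_dark(_cube(data), exclusion_radius_px=0)
    assert not mask.valid[5, 5]
    assert mask.valid[4, 4]


def test_missing_band_names_raise():
    from mscolo.bands import BandSpec

    bands = tuple(BandSpec(float(400 + i * 30), f"B{i}") for i in range(7))
    img = MultiSpectralImage(np.full((5, 5, 7), 0.5), bands)
    with pytest.raises(ConfigurationError):
        exclude_specular_and_dark(img)


def test_default_cohort_exclusion_near_one_percent():
    """On the full-size default generator, the dark-pixel rule plus 5 px
    dilation removes about 1% of the pixels."""
    params = CohortParams(n_animals=1, seed=2)
    sample = generate_cohort(params)[0]
    frac = exclude_specular_and_dark(sample.image).fraction_excluded()
    assert 0.002 < frac < 0.03


# ---------------------------------------------------------------------------
# Gaussian filtering


def test_constant_image_unchanged(flat_image):
    out = gaussian_filter_stack(flat_image, 7, 1.0)
    np.testing.assert_allclose(out.data, flat_image.data, atol=1e-12)


def test_impulse_response_equals_tabulated_kernel():
    """The filter realizes exactly the truncated normalized 7x7 sigma=1
    kernel, tabulated here independently."""
    data = np.zeros((21, 21, 7))
    data[10, 10, :] = 1.0
    out = gaussian_filter_stack(_cube(data), 7, 1.0)
    expected = np.empty((7, 7))
    for i in range(7):
        for j in range(7):
            expected[i, j] = np.exp(-((i - 3) ** 2 + (j - 3) ** 2) / 2.0)
    expected /= expected.sum()
    np.testing.assert_allclose(out.data[7:14, 7:14, 0], expected, atol=1e-12)
    assert np.all(out.data[:7, :, 0] == 0)


def test_filter_reduces_noise_variance():
    rng = np.random.default_rng(0)
    data = np.clip(0.5 + rng.normal(0, 0.05, (40, 40, 7)), 0, 1)
    out = gaussian_filter_stack(_cube(data), 7, 1.0)
    assert out.data[:, :, 0].var() < data[:, :, 0].var() / 2


def test_even_kernel_size_rejected(flat_image):
    with pytest.raises(ParameterError):
        gaussian_filter_stack(flat_image, 6, 1.0)


# ---------------------------------------------------------------------------
# lesion margin


def test_empty_mask_excludes_nothing():
    mask = exclude_lesion_margin(PixelMask(np.zeros((12, 12), bool)))
    assert mask.valid.all()


def test_margin_width_matches_distance_transform_oracle():
    """A one-pixel lesion line excludes a band whose width matches a
    brute-force distance computation on both sides."""
    lesion = np.zeros((21, 21), dtype=bool)
    lesion[10, :] = True
    mask = exclude_lesion_margin(PixelMask(lesion), margin_px=5)
    expected = np.ones((21, 21), dtype=bool)
    for r in range(21):
        for c in range(21):
            dist = min(abs(r - 10), 10)  # distance to the lesion row
            if lesion[r, c]:
                dist = 1  # lesion pixels border healthy rows directly
            if dist <= 5:
                expected[r, c] = False
    assert np.array_equal(mask.valid, expected)


def test_margin_symmetric_for_centred_disc(disc_mask):
    mask = exclude_lesion_margin(disc_mask, margin_px=4)
    assert np.array_equal(mask.valid, mask.valid[::-1, :])
    assert np.array_equal(mask.valid, mask.valid[:, ::-1])
    # both sides of the boundary lose pixels
    assert (~mask.valid & disc_mask.valid).any()
    assert (~mask.valid & ~disc_mask.valid).any()


# ---------------------------------------------------------------------------
# normalization


def test_normalize_divides_by_band_max(tiny_cohort):
    img = tiny_cohort[0].image
    normed, record = normalize(img)
    assert np.allclose(normed.data.reshape(-1, 7).max(axis=0), 1.0)
    np.testing.assert_allclose(
        record.per_band_max, img.data.reshape(-1, 7).max(axis=0))


def test_normalize_roundtrip_and_scale_invariance(tiny_cohort):
    img = tiny_cohort[0].image
    normed, record = normalize(img)
    np.testing.assert_allclose(denormalize(normed, record).data, img.data,
                               rtol=1e-12)
    scaled = MultiSpectralImage(img.data * 0.37, img.bands)
    normed2, _ = normalize(scaled)
    np.testing.assert_allclose(normed2.data, normed.data, rtol=1e-9)


def test_all_zero_band_raises():
    data = np.full((8, 8, 7), 0.5)
    data[:, :, 2] = 0.0
    with pytest.raises(NormalizationError):
        normalize(_cube(data))


# ---------------------------------------------------------------------------
# noise estimation


def _linear_cube(rng, shape=(20, 20), noise=0.0):
    """Bands as exact linear mixtures of two latent fields (+ noise)."""
    a = rng.random(shape)
    b = rng.random(shape)
    coefs = rng.random((7, 2)) + 0.1
    cube = np.stack([c0 * a + c1 * b for c0, c1 in coefs], axis=2)
    if noise:
        cube = cube + rng.normal(0, noise, cube.shape)
    return cube


def test_multilinear_residuals_vanish_on_linear_bands():
    rng = np.random.default_rng(0)
    cube = _linear_cube(rng)
    noise = estimate_noise(cube, MNFConfig(noise_estimator="multilinear"))
    assert np.abs(noise).max() < 1e-8


def test_noise_variance_recovered_within_factor_two():
    """Known additive noise: the typical estimated band-noise variance sits
    within a factor two of the truth (individual bands can inflate more
    because the regressors themselves are noisy)."""
    rng = np.random.default_rng(1)
    true_sd = 0.02
    cube = _linear_cube(rng, shape=(30, 30), noise=true_sd)
    noise = estimate_noise(cube, MNFConfig(noise_estimator="multilinear"))
    est_var = noise.reshape(-1, 7).var(axis=0)
    ratio = est_var / true_sd ** 2
    assert 0.5 < np.median(ratio) < 2.0
    assert np.all(ratio > 0.25) and np.all(ratio < 4.0)


def test_svr_and_multilinear_rank_band_noise_consistently():
    """Both estimators order the bands the same way when each band carries
    a different known noise level."""
    rng = np.random.default_rng(2)
    cube = _linear_cube(rng)
    sds = np.linspace(0.005, 0.08, 7)
    cube = cube + rng.normal(0, 1, cube.shape) * sds[None, None, :]
    var_ml = estimate_noise(cube, MNFConfig(noise_estimator="multilinear")
                            ).reshape(-1, 7).var(axis=0)
    var_svr = estimate_noise(cube, MNFConfig(noise_estimator="svr")
                             ).reshape(-1, 7).var(axis=0)
    from scipy.stats import spearmanr

    rho, _ = spearmanr(var_ml, var_svr)
    assert rho > 0.85


def test_constant_tile_falls_back_with_warning(caplog):
    import logging

    cube = np.full((10, 10, 7), 0.5)
    with caplog.at_level(logging.WARNING, logger="mscolo.preprocessing"):
        noise = estimate_noise(cube, MNFConfig(noise_estimator="svr"))
    assert "shift-difference" in caplog.text
    assert np.allclose(noise, 0.0)


# ---------------------------------------------------------------------------
# MNF


def test_mnf_ndrop_zero_is_identity(tiny_cohort):
    img = tiny_cohort[0].image
    normed, _ = normalize(img)
    out = mnf_denoise(normed, None, MNFConfig(n_drop=0, noise_estimator="multilinear"))
    assert np.abs(out.data - normed.data).max() < 1e-8


def test_mnf_denoises_rank_one_cube():
    """Rank-1 spectral signal plus weak i.i.d. noise: dropping the three
    trailing components reduces the mean squared error to the clean cube."""
    rng = np.random.default_rng(3)
    spatial = rng.random((24, 24))
    spectrum = np.linspace(0.3, 1.0, 7)
    clean = spatial[:, :, None] * spectrum[None, None, :]
    noisy = np.clip(clean + rng.normal(0, 0.02, clean.shape), 0, None)
    out = mnf_denoise(_cube(noisy), None,
                      MNFConfig(n_drop=3, noise_estimator="multilinear"))
    mse_raw = np.mean((noisy - clean) ** 2)
    mse_out = np.mean((out.data - clean) ** 2)
    assert mse_out < mse_raw


def test_mnf_preserves_shape_and_band_count(tiny_cohort):
    normed, _ = normalize(tiny_cohort[0].image)
    out = mnf_denoise(normed, None, MNFConfig(noise_estimator="multilinear"))
    assert out.data.shape == normed.data.shape


def test_mnf_rejects_bad_ndrop(tiny_cohort):
    normed, _ = normalize(tiny_cohort[0].image)
    with pytest.raises(ParameterError):
        mnf_denoise(normed, None, MNFConfig(n_drop=7))


# ---------------------------------------------------------------------------
# full chain


def test_preprocess_stage_order_audited(tiny_cohort):
    res = preprocess(tiny_cohort[0].image, tiny_cohort[0].lesion_mask,
                     PreprocessConfig(mnf=MNFConfig(noise_estimator="multilinear")))
    assert [s.stage for s in res.stages] == [
        "exclude_specular_and_dark", "gaussian_filter_stack",
        "exclude_lesion_margin", "normalize", "mnf_denoise", "denormalize",
        "gaussian_filter_stack"]


def test_combined_mask_is_and_of_stage_masks(tiny_cohort):
    """The returned validity mask equals the brute-force AND of the
    specular/dark mask and the margin mask."""
    s = tiny_cohort[0]
    cfg = PreprocessConfig(mnf=MNFConfig(noise_estimator="multilinear"))
    res = preprocess(s.image, s.lesion_mask, cfg)
    dark = exclude_specular_and_dark(s.image, cfg.dark_threshold_fraction,
                                     cfg.dark_exclusion_radius_px)
    margin = exclude_lesion_margin(s.lesion_mask, cfg.margin_px)
    assert np.array_equal(res.valid.valid, dark.valid & margin.valid)
    # exclusion stages only ever shrink the valid set
    assert res.valid.valid.sum() <= dark.valid.sum()
    assert res.valid.valid.sum() <= margin.valid.sum()


def test_zero_noise_image_changes_only_by_smoothing():
    p = tiny_params(noise_sd=0.0, texture_amplitude=0.0, specular_spot_count=0,
                    vignette_strength=0.0)
    s = generate_cohort(p)[0]
    res = preprocess(s.image, s.lesion_mask,
                     PreprocessConfig(mnf=MNFConfig(noise_estimator="multilinear")))
    smoothed = gaussian_filter_stack(
        gaussian_filter_stack(s.image, 7, 1.0), 11, 2.0)
    np.testing.assert_allclose(res.image.data, smoothed.data, atol=2e-3)


def test_preprocess_reduces_mse_to_clean_signal():
    """On a noisy cohort the processed image is closer to the noise-free
    image than the raw input is."""
    clean_p = tiny_params(noise_sd=0.0, specular_spot_count=0)
    noisy_p = tiny_params(noise_sd=0.03, specular_spot_count=0)
    clean = generate_cohort(clean_p)[0]
    noisy = generate_cohort(noisy_p)[0]
    res = preprocess(noisy.image, noisy.lesion_mask,
                     PreprocessConfig(mnf=MNFConfig(noise_estimator="multilinear")))
    mse_raw = np.mean((noisy.image.data - clean.image.data) ** 2)
    mse_out = np.mean((res.image.data - clean.image.data) ** 2)
    assert mse_out < mse_raw
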