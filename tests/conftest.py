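import numpy as np
import pytest

from mscolo import CohortParams, generate_cohort
from mscolo.bands import DEFAULT_BANDS
from mscolo.types import MultiSpectralImage, PixelMask


def tiny_params(**overrides) -> CohortParams:
    base = dict(
        n_animals=2, image_shape=(48, 48), lesion_count_range=(1, 2),
        lesion_radius_range=(6.0, 9.0), specular_spot_count=1,
        specular_radius_px=2.0, vignette_strength=0.5, noise_sd=0.01, seed=42)
    base.update(overrides)
    return CohortParams(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two 48x48 animals with default contrast; reused across tests."""
    return generate_cohort(tiny_params())


@pytest.fixture()
def flat_image():
    """Spatially constant cube with distinct per-band levels."""
    levels = np.linspace(0.2, 0.9, 7)
    data = np.ones((20, 20, 7)) * levels[None, None, :]
    return MultiSpectralImage(data, DEFAULT_BANDS)


@pytest.fixture()
def disc_mask():
    # odd grid so the disc centre sits on a pixel and mirroring is exact
    yy, xx = np.mgrid[0:49, 0:49]
    return PixelMask(np.hypot(yy - 24, xx - 24) <= 10, provenance="label")
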