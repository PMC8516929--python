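import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slidemine.synthetic import SyntheticSlideSpec, generate_slide

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SPEC = SyntheticSlideSpec(
    width_px=512,
    height_px=512,
    n_tissue_blobs=2,
    lesion=True,
    n_lesion_regions=2,
    lesion_region_diameter_px=100,
    seed=7,
)


@pytest.fixture(scope="session")
def pos_result():
    """One positive synthetic slide with two lesion regions."""
    return generate_slide(SMALL_SPEC)


@pytest.fixture(scope="session")
def neg_result():
    """One negative synthetic slide."""
    spec = SyntheticSlideSpec(
        width_px=512, height_px=512, n_tissue_blobs=2, lesion=False, seed=11
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
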