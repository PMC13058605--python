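import math

import pytest

from sonogold.synthetic import SceneSpec


@pytest.fixture
def clean_scene_spec() -> SceneSpec:
    """Zero-noise, non-overlapping scene with safely supra-resolution clusters."""
    return SceneSpec(
        image_shape=(512, 512),
        pixel_size=0.2,
        n_clusters=20,
        diameter_log_mu=math.log(0.8),
        diameter_log_sigma=0.3,
        psf_sigma=0.1,
        noise_sd=0.0,
        allow_overlap=False,
        seed=7,
    )
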