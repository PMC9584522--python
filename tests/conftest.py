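import numpy as np
import pytest

from plumaquant import ImageFrame, SceneSpec, generate_texture


@pytest.fixture(scope="session")
def isotropic_frame() -> ImageFrame:
    """One isotropic texture frame used by several estimator tests."""
    return generate_texture(
        SceneSpec(
            width_px=512, height_px=512, pixel_size_um=0.5,
            correlation_length_um=1.5, noise_sd=2.0, seed=11,
        )
    )


@pytest.fixture()
def disc_frame_factory():
    """Factory for noise-free frames of constant-intensity discs."""

    def build(centers_yx, radius_px=15, shape=(200, 200), value=200.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        img = np.zeros(shape)
        for cy, cx in centers_yx:
            img = np.maximum(
                img,
                np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2, value, 0.0),
            )
        return ImageFrame(img, 1.0)

    return build
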