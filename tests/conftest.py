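import numpy as np
import pytest

from fig3d.mesh_io import Facet, FacetSoup
from fig3d.texture import TextureImage


@pytest.fixture
def rng():
    return np.random.default_rng(20131)


@pytest.fixture
def random_soup(rng):
    """50 random triangles, one shared colour."""
    facets = [
        Facet(rng.uniform(-1, 1, (3, 3)), rng.standard_normal(3), (0.5, 0.5, 0.5))
        for _ in range(50)
    ]
    return FacetSoup(facets)


def gradient_texture(w=64, h=64, alpha=255):
    """Smooth RGB gradient with constant alpha."""
    x = np.linspace(0, 255, w)
    y = np.linspace(0, 255, h)
    xx, yy = np.meshgrid(x, y)
    px = np.stack(
        [xx, yy, (xx + yy) / 2, np.full_like(xx, float(alpha))], axis=-1
    )
    return TextureImage(np.round(px).astype(np.uint8))


@pytest.fixture
def opaque_gradient():
    return gradient_texture()


@pytest.fixture
def transparent_gradient():
    """Smooth 128x128 texture with thousands of distinct colours and a
    spatially varying alpha channel (so it takes the palette path)."""
    w = h = 128
    x = np.linspace(0, 255, w)
    y = np.linspace(0, 255, h)
    xx, yy = np.meshgrid(x, y)
    a = 255 * (0.2 + 0.8 * (xx / 255) * (yy / 255))
    px = np.stack([xx, yy, 255 - xx, a], axis=-1)
    t = TextureImage(np.round(px).astype(np.uint8))
    assert len(np.unique(t.pixels.reshape(-1, 4), axis=0)) > 4000
    return t
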