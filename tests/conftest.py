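import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octqc import BoundaryCurve, SceneConfig, generate_clean_scan, rasterize

settings.register_profile(
    "octqc",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("octqc")


def flat_scene(
    width: int = 32,
    depth: int = 80,
    rows=(10, 20, 30, 40, 50, 60),
    layer_means=(0.1, 0.3, 0.5, 0.7, 0.9),
    band: int = 20,
    **kwargs,
) -> SceneConfig:
    """A scene with constant (flat) boundary rows — easy to reason about."""
    return SceneConfig(
        width=width,
        depth=depth,
        layer_means=layer_means,
        boundary_params=[BoundaryCurve(offset=r) for r in rows],
        band=band,
        **kwargs,
    )


@pytest.fixture
def small_flat():
    """(scene, clean scan, boundaries, mask) for a small flat-layer phantom."""
    scene = flat_scene()
    clean, bs = generate_clean_scan(scene)
    mask = rasterize(bs, depth=scene.depth, band=scene.band)
    return scene, clean, bs, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
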