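import numpy as np
import pytest

from slimloc import (
    SimScene,
    USVSegment,
    four_mic_geometry,
    render_scene,
    three_mic_geometry,
)


@pytest.fixture(scope="session")
def geom4():
    return four_mic_geometry()


@pytest.fixture(scope="session")
def geom3():
    return three_mic_geometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def rendered_scene(geometry, position, snr_db=20.0, seed=0, **kw):
    """Render one chirp scene and return (recording, segment, scene)."""
    scene = SimScene(position, snr_db=snr_db, seed=seed, **kw)
    rec = render_scene(scene, geometry)
    seg = USVSegment(scene.onset_s, scene.onset_s + scene.duration_ms * 1e-3)
    return rec, seg, scene


def random_sources(geometry, n, rng, inset=20.0):
    """Random source positions strictly inside the platform."""
    hx, hy = geometry.platform_half_extent
    return rng.uniform([-hx + inset, -hy + inset], [hx - inset, hy - inset], (n, 2))
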