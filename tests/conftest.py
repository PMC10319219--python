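import numpy as np
import pytest

from floodscope.pipeline import PipelineConfig, run_end_to_end
from floodscope.raster import Affine, Raster, NODATA_FLOAT, NODATA_INT
from floodscope.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raster(values, pixel_size=10.0, nodata=NODATA_FLOAT, crs_id="LOCAL:m"):
    values = np.asarray(values)
    t = Affine.from_origin(0.0, values.shape[0] * pixel_size, pixel_size)
    return Raster(values, t, crs_id, nodata)


def make_binary(values, pixel_size=10.0):
    return make_raster(np.asarray(values, dtype=np.uint8), pixel_size, nodata=NODATA_INT)


@pytest.fixture
def raster_factory():
    return make_raster


@pytest.fixture
def binary_factory():
    return make_binary


@pytest.fixture(scope="session")
def small_scene_config():
    # compact scene for unit-level work; default layout scales with shape
    return SceneConfig(shape=(80, 80), seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_scene_config):
    return generate_scene(small_scene_config)


@pytest.fixture(scope="session")
def noiseless_result():
    """End-to-end run on a speckle-free, texture-free scene."""
    cfg = PipelineConfig(
        scene=SceneConfig(looks=None, sigma=0.0),
        n_samples=900,
        seed=11,
    )
    return run_end_to_end(cfg)


@pytest.fixture(scope="session")
def speckled_result():
    """End-to-end run at the default study conditions (L = 10 speckle)."""
    return run_end_to_end(PipelineConfig(seed=5))
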