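import numpy as np
import pytest

from plantspace import CameraModel, RunConfig, SceneSpec, render_scene


@pytest.fixture
def cam2m() -> CameraModel:
    """Standard trial camera: 2 m, 72 deg diagonal AOV, 4:3 frame."""
    return CameraModel.from_degrees(2.0, 72.0, 960, 720)


@pytest.fixture
def clean_scene(cam2m):
    """Noise-free-truth clean scene: no weeds, no residue, no jitter."""
    spec = SceneSpec(camera=cam2m, interval=0.18, rng_seed=42)
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture
def default_config(cam2m) -> RunConfig:
    return RunConfig(camera=cam2m, plant_height_m=0.10)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
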