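import numpy as np
import pandas as pd
import pytest

import gazedecode as gd
from gazedecode.data import FIXATION_COLUMNS


@pytest.fixture(scope="session")
def geometry():
    # 1920x1080 over a 24-inch 16:9 panel at 58 cm: ~36.6 px/dva
    return gd.ScreenGeometry.from_diagonal(58.0, (1920, 1080), 24.0)


@pytest.fixture(scope="session")
def unit_geometry():
    # 1 px per cm at 57.29 cm: almost exactly 1 px per dva
    return gd.ScreenGeometry(57.29, (400, 300), (400.0, 300.0))


@pytest.fixture(scope="session")
def scene():
    return gd.SaliencyScene.default()


@pytest.fixture(scope="session")
def null_dataset(scene):
    """Two-condition dataset with no planted effect."""
    return gd.sample_dataset(scene, gd.EffectSpec(delta=0.0),
                             gd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def effect_dataset(scene):
    """Dataset with a moderate planted weight shift toward the target."""
    return gd.sample_dataset(scene, gd.EffectSpec(delta=0.3),
                             gd.SimConfig(seed=12))


@pytest.fixture(scope="session")
def render64():
    return gd.RenderConfig(output_size_px=(64, 64))


def make_dataset(rows, geometry=None, frames=None):
    """Build a GazeDataset from (participant, image, condition, rep, idx,
    x, y) tuples with default geometry/frames."""
    geometry = geometry or gd.ScreenGeometry(57.29, (400, 300),
                                             (400.0, 300.0))
    df = pd.DataFrame(
        [(*r, 200.0, 0.0) if len(r) == 7 else r for r in rows],
        columns=FIXATION_COLUMNS,
    )
    if frames is None:
        frames = {im: gd.StimulusFrame(im, (400, 300))
                  for im in df["image"].unique()}
    return gd.GazeDataset(df, geometry, frames)


@pytest.fixture
def toy_dataset():
    rows = []
    for rep in (1, 2):
        for i in range(1, 4):
            rows.append(("p1", "imgA", "sound", rep, i, 50.0 + i, 60.0))
            rows.append(("p1", "imgA", "no_sound", rep, i, 300.0 - i, 200.0))
    return make_dataset(rows)
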