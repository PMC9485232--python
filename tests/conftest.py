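import numpy as np
import pytest

from stereofish import ScaleCalibrator, SceneConfig, default_rig


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def hyperbola_model(rig):
    """Cubic scale model fit on noiseless analytic scale = B*1e6/d data.

    Trained over disparities 140-320 px, a span over which a cubic can
    represent the hyperbola to well under 1% relative error.
    """
    d = np.linspace(140.0, 320.0, 200)
    s = rig.baseline * 1e6 / d
    return ScaleCalibrator(degree=3, alpha=0.0).fit(d, s)


@pytest.fixture(scope="session")
def calib_scene_cfg(rig):
    """Default calibration geometry: distances spanning disparities 140-600 px."""
    return SceneConfig.for_disparity_range(rig, seed=11)
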