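import logging

import numpy as np
import pytest

from phytoproxy.geometry import Rect
from phytoproxy.synthetic import SceneLayout, StressScenario, render_scene

# Quiet the per-ROI "no plant pixels" warnings during bulk processing tests.
logging.getLogger("phytoproxy.segmentation").setLevel(logging.ERROR)


#: Small scene for fast unit tests (full default layout is used in the
#: acceptance suite).
TINY_LAYOUT = SceneLayout(
    height=30,
    width=60,
    white_patch=Rect(0, 6, 48, 60),
    plant_region=Rect(6, 30, 0, 60),
)

#: Noise-free variant for exactness checks.
CLEAN_LAYOUT = SceneLayout(
    height=30,
    width=60,
    white_patch=Rect(0, 6, 48, 60),
    plant_region=Rect(6, 30, 0, 60),
    noise_sigma=0.0,
    pigment_jitter=0.0,
    stress_spread=0.0,
)


@pytest.fixture(scope="session")
def pea_control_bundle():
    return render_scene(StressScenario("pea", "control"), day=1, layout=TINY_LAYOUT, seed=7)


@pytest.fixture(scope="session")
def wheat_control_bundle():
    return render_scene(StressScenario("wheat", "control"), day=1, layout=TINY_LAYOUT, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)
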