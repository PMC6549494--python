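import numpy as np
import pytest

import crowdsim
from crowdsim import retina as ret
from crowdsim import stimuli as stim


@pytest.fixture(scope="session")
def geometry():
    return stim.SceneGeometry()


@pytest.fixture(scope="session")
def exp1b_specs():
    return stim.condition_table("exp1b")


@pytest.fixture(scope="session")
def vernier_scene(exp1b_specs, geometry):
    """Unflanked Vernier display at 3.89 deg."""
    return stim.render_vernier(exp1b_specs[0], geometry)


@pytest.fixture(scope="session")
def inner_scene(exp1b_specs, geometry):
    return stim.render_vernier(exp1b_specs[1], geometry)


@pytest.fixture(scope="session")
def retina_params():
    return ret.RetinaParams()


@pytest.fixture(scope="session")
def vernier_retina(vernier_scene, retina_params):
    """Full retina stage on the unflanked Vernier scene (cached)."""
    return ret.retina_pipeline(vernier_scene, retina_params)


def bar_scene(eccentricity_deg, geometry=None, height_deg=0.5, width_deg=0.06):
    """A single dark vertical bar at a given eccentricity (test helper)."""
    geometry = geometry or stim.SceneGeometry()
    img = np.full(geometry.shape, stim.BACKGROUND)
    r = geometry.fixation[0]
    c = geometry.col_of(eccentricity_deg)
    h = geometry.px(height_deg) / 2.0
    w = max(1, int(round(geometry.px(width_deg))))
    r0, r1 = int(round(r - h)), int(round(r + h))
    c0 = int(round(c - w / 2.0))
    img[r0:r1, c0:c0 + w] = stim.FOREGROUND
    return stim.VisualScene(img, geometry.deg_per_pixel, geometry.fixation,
                            meta={"label": f"bar{eccentricity_deg:g}"})


@pytest.fixture(scope="session")
def small_run_config():
    """Tiny but complete experiment configuration for runner tests."""
    return crowdsim.RunConfig(experiment_id="exp1b", n_trials=3, n_sessions=1,
                              master_seed=11)
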