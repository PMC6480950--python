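import numpy as np
import pytest

import lurkit as lk


@pytest.fixture(scope="session")
def small_scene():
    """A dense 16-station scene with measurements (population R² 0.75)."""
    scene = lk.generate_scene(lk.small_scene_config(seed=7))
    design, y = lk.generate_measurements(scene)
    return scene, design, y


@pytest.fixture(scope="session")
def headline_experiment():
    """The reference recovery experiment: 20 replicate scenes at the
    default study conditions (73 stations x 8 years, ~150 candidates,
    population R² 0.75), each scored against its planted truth and
    cross-validated site-grouped 10-fold.  Shared session-wide because it
    is the single most expensive computation in the suite."""
    return lk.recovery_experiment(lk.SceneConfig(seed=1), n_replicates=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
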