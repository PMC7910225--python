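"""Shared fixtures: small phantoms and end-to-end pipeline runs.

The two pipeline fixtures are session-scoped because they are the expensive
part of the suite (a full simulate -> preprocess -> reconstruct -> stitch ->
segment chain each); several test modules assert different properties of
the same runs.
"""

import numpy as np
import pytest

from mosaictomo.config import desk_scale_config
from mosaictomo.phantom import make_foam_phantom
from mosaictomo.pipeline import run_pipeline


@pytest.fixture(scope="session")
def foam_phantom():
    """Mid-size foam phantom with known air-volume ground truth."""
    return make_foam_phantom((96, 128, 128), target_air_fraction=0.5, seed=3)


@pytest.fixture(scope="session")
def small_foam():
    """Small, fast foam phantom for registration/projection tests."""
    return make_foam_phantom((64, 96, 96), target_air_fraction=0.5, seed=5)


@pytest.fixture(scope="session")
def pipeline_static():
    """Full pipeline run on a static (undeformed) 2x1x2 mosaic."""
    return run_pipeline(desk_scale_config(seed=1, deformed=False))


@pytest.fixture(scope="session")
def pipeline_deformed():
    """Full pipeline run with slow tissue deformation between tiles."""
    return run_pipeline(desk_scale_config(seed=1, deformed=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
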