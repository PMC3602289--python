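import numpy as np
import pytest

from torsofuse import phantom
from torsofuse.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def study():
    """Default synthetic patient: 50-degree curve, seeded prone perturbation."""
    return phantom.generate_study(seed=7)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full three-method pipeline run on a seeded phantom."""
    return run_pipeline(PipelineConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """Seeded random proper rigid transform."""
    from scipy.spatial.transform import Rotation

    from torsofuse.geometry import RigidTransform

    R = Rotation.from_euler("xyz", rng.uniform(-180, 180, 3), degrees=True).as_matrix()
    return RigidTransform(R, rng.uniform(-100, 100, 3))
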