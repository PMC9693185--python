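import numpy as np
import pytest

from skelsuite import PoseSequence, default_skeleton


@pytest.fixture(scope="session")
def skel():
    return default_skeleton()


@pytest.fixture
def static_pose(skel):
    """A valid static 3D pose repeated over 10 frames (from the generator's
    rest configuration, so bone geometry is realistic)."""
    from skelsuite import SyntheticPoseConfig, gen_pose_sequence

    cfg = SyntheticPoseConfig(n_frames=1, motion_amplitude=0.0, jump=False, seed=0)
    truth, _ = gen_pose_sequence(cfg)
    coords = np.repeat(truth.coords, 10, axis=0)
    return PoseSequence(
        coords=coords,
        visible=np.ones((10, 18), dtype=bool),
        skeleton=truth.skeleton,
        units="meters",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
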