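import numpy as np
import pytest

from rehabscore.motion_model import MotionSequence
from rehabscore.synthetic_motion import generate_reference


@pytest.fixture(scope="session")
def standing_ref() -> MotionSequence:
    """Noiseless standing diagonal-raise reference (8 s at 30 fps)."""
    return generate_reference("standing_diagonal")


@pytest.fixture(scope="session")
def seated_ref() -> MotionSequence:
    """Noiseless seated external-rotation reference (8 s at 30 fps)."""
    return generate_reference("seated_rotation")


def make_random_sequence(
    n: int = 6, k: int = 33, seed: int = 0, fps: float = 30.0
) -> MotionSequence:
    """A structurally valid random sequence for serialization/scoring tests."""
    rng = np.random.default_rng(seed)
    return MotionSequence(
        exercise_id="random",
        fps=fps,
        source="synthetic",
        t=np.arange(n) / fps,
        coords=rng.uniform(0.1, 0.9, (n, k, 3)),
        visibility=rng.uniform(0.5, 1.0, (n, k)),
        landmark_indices=np.arange(k),
    )


@pytest.fixture()
def random_seq() -> MotionSequence:
    return make_random_sequence()
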