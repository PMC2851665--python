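import numpy as np
import pytest

from amide2d.structures import Residue, Structure
from amide2d.synthetic import MotifSpec, build_backbone, make_beta3s_conformers


@pytest.fixture(scope="session")
def helix12() -> Structure:
    """Ideal 12-residue α-helix."""
    n = 12
    spec = MotifSpec("helix", np.full(n, -57.0), np.full(n, -47.0), sequence="A" * n)
    return build_backbone(spec)


@pytest.fixture(scope="session")
def extended20() -> Structure:
    """Fully extended isolated 20-mer (no H-bond partners)."""
    n = 20
    spec = MotifSpec("strand", np.full(n, -139.0), np.full(n, 135.0), sequence="A" * n)
    return build_backbone(spec)


@pytest.fixture(scope="session")
def conformers() -> dict[str, Structure]:
    """The five synthetic Beta3s conformers at seed 0 (cached)."""
    return make_beta3s_conformers(0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(0.0, 20.0, size=3)
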