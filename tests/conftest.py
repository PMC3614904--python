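import numpy as np
import pytest

from restrelax import templates as T
from restrelax.fixtures import FixtureSpec, build_peptide, fixture_suite, plant_defects
from restrelax.relax import RelaxConfig


@pytest.fixture(scope="session")
def suite():
    """The standard synthetic benchmark suite (seed 1)."""
    return fixture_suite(1)


@pytest.fixture(scope="session")
def fast_cfg():
    """Relax configuration scaled for mini-protein test fixtures."""
    return RelaxConfig(max_min_iters=80, min_tolerance=1e-2, seed=0)


@pytest.fixture
def helix10():
    return build_peptide(FixtureSpec("AVLSKEALRS", "helix"))


@pytest.fixture
def polyala10():
    return build_peptide(FixtureSpec("A" * 10, "helix"))


@pytest.fixture
def clash16():
    """16-residue helix with one planted clash rotamer (residue 8)."""
    spec = FixtureSpec("AVLSKEAFKSAAQWEL", "helix",
                       [(8, "clash_rotamer", None)], seed=2)
    return plant_defects(build_peptide(spec), spec)


def rigid_motion(rng):
    """A random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=10.0, size=3)
    return R, t
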