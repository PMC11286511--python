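import numpy as np
import pytest
from hypothesis import settings

from helifil import fixtures as fx
from helifil import helical_geometry as hg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle_subunit():
    """The reference 3-helix, 20-residue/helix poly-alanine subunit."""
    return fx.make_bundle_subunit(fx.BundleSpec(3, 20, 7.0, seed=1))


@pytest.fixture(scope="session")
def dphf19_filament(bundle_subunit):
    """40 copies of the reference subunit under the DpHF19 preset screw."""
    return hg.propagate(bundle_subunit, fx.get_preset("DpHF19").transform, 40)


@pytest.fixture(scope="session")
def fragment_db():
    return fx.make_fragment_db(100, seed=3)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
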