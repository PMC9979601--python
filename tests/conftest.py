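import numpy as np
import pytest

from alfgp.geometry import MolecularGeometry
from alfgp.synthetic import load_template


@pytest.fixture
def water() -> MolecularGeometry:
    # bent triatomic with two slightly inequivalent O-H distances
    return MolecularGeometry(
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    )


@pytest.fixture(scope="session")
def glycine19() -> MolecularGeometry:
    return load_template("glycine19")


@pytest.fixture(scope="session")
def ibuprofen33() -> MolecularGeometry:
    return load_template("ibuprofen33")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
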