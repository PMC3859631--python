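import numpy as np
import pytest

from poremut import synthetic
from poremut.structure import AnalysisConfig


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def bundle_dimer():
    """Two-helix poly-Ala dimer plus its geometric ground truth."""
    return synthetic.make_bundle_dimer()


@pytest.fixture(scope="session")
def barrel():
    """Ring-stacked carbon cage with a cylindrical pore of known clearance."""
    return synthetic.make_barrel()


@pytest.fixture(scope="session")
def single_sphere():
    return synthetic.make_spheres([[0.0, 0.0, 0.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
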