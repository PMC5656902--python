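import numpy as np
import pytest

from cpaselect import find_catalyst_anchors
from cpaselect.fixtures import make_catalyst_3d


@pytest.fixture(scope="session")
def parent_catalyst():
    """The 3,3'-H BINOL phosphoric acid, embedded in 3D."""
    mol = make_catalyst_3d("H")
    return mol, find_catalyst_anchors(mol)


@pytest.fixture(scope="session")
def phenyl_catalyst():
    mol = make_catalyst_3d("Ph")
    return mol, find_catalyst_anchors(mol)


@pytest.fixture(scope="session")
def anthryl_catalyst():
    mol = make_catalyst_3d("9-anthryl")
    return mol, find_catalyst_anchors(mol)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
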