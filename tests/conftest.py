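import numpy as np
import pytest

from tmrepack.fixtures import (
    FixtureSpec,
    make_ideal_bundle,
    make_ligand_fixture,
    make_pocket_bundle,
    pocket_target_spec,
)
from tmrepack.ligands import LigandConformer


@pytest.fixture(scope="session")
def ideal_bundle():
    return make_ideal_bundle(FixtureSpec())


@pytest.fixture(scope="session")
def pocket_bundle():
    return make_pocket_bundle()


@pytest.fixture(scope="session")
def pocket_spec(pocket_bundle):
    return pocket_target_spec(pocket_bundle)


@pytest.fixture(scope="session")
def dopamine():
    return LigandConformer(make_ligand_fixture("toy_catechol_amine"))


@pytest.fixture(scope="session")
def toy_cation():
    return LigandConformer(make_ligand_fixture("toy_cation"))


@pytest.fixture(scope="session")
def npa():
    return LigandConformer(make_ligand_fixture("R-NPA"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
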