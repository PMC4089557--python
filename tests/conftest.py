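import random

import pytest

from elucid.chem_graph import from_smiles
from elucid.fixtures import (
    FixtureSpec,
    make_closed_loop_problem,
    make_np_corpora,
    make_reference_set,
)
from elucid.hose_index import build_index
from elucid.np_model import train_fragment_model

CLOSED_LOOP_ANSWER_SMILES = "CC1CCOC1"  # 2-methyl-tetrahydrofuran, 6 heavy atoms


@pytest.fixture(scope="session")
def ethanol():
    return from_smiles("CCO")


@pytest.fixture(scope="session")
def dimethyl_ether():
    return from_smiles("COC")


@pytest.fixture(scope="session")
def benzene():
    return from_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def methane():
    return from_smiles("C")


@pytest.fixture(scope="session")
def closed_loop_answer():
    return from_smiles(CLOSED_LOOP_ANSWER_SMILES)


@pytest.fixture(scope="session")
def reference_set(closed_loop_answer):
    """Synthetic shift reference set, disjoint from the closed-loop answer."""
    return make_reference_set(
        FixtureSpec(n_molecules=100, seed=3), exclude={closed_loop_answer.key}
    )


@pytest.fixture(scope="session")
def shift_index(reference_set):
    return build_index(reference_set)


@pytest.fixture(scope="session")
def np_corpora():
    return make_np_corpora(FixtureSpec(n_molecules=25, seed=3))


@pytest.fixture(scope="session")
def fragment_model(np_corpora):
    np_set, syn_set = np_corpora
    return train_fragment_model(np_set, syn_set)


@pytest.fixture(scope="session")
def closed_loop(closed_loop_answer, shift_index):
    """(formula, spectrum, answer) with spectrum = index's own predictions."""
    return make_closed_loop_problem(closed_loop_answer, shift_index)


@pytest.fixture()
def rng():
    return random.Random(20240705)
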