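import numpy as np
import pytest
from hypothesis import settings

from umamipep import (
    CollagenGeneratorConfig,
    ProteaseRule,
    ProteinSequence,
    generate_collagen_like,
    load_catalog,
    load_protease_set,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protease_set():
    return load_protease_set()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture
def pepsin_like():
    """The broad acid-protease rule: cleaves C-terminal to F,L,G,Y,A,E,Q,T."""
    return ProteaseRule(
        name="pepsin-like", ec_number="3.4.23.1", side="cterm",
        p1_residues=frozenset("FLGYAEQT"),
    )


@pytest.fixture(scope="session")
def collagen_chain():
    return generate_collagen_like(CollagenGeneratorConfig(n_triplets=450, seed=1))


@pytest.fixture
def random_sequences():
    """Deterministic random 30-mers over the canonical alphabet."""
    rng = np.random.default_rng(42)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        ProteinSequence(id=f"r{i}", residues="".join(rng.choice(alphabet, size=30)))
        for i in range(25)
    ]
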