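import pytest

from mitochar import datasets
from mitochar.simulate import GenomeSpec, generate_mitogenome


@pytest.fixture(scope="session")
def annotation():
    """The bundled 38-feature reference annotation (no sequence)."""
    return datasets.load_annotation()


@pytest.fixture(scope="session")
def ground_order():
    return datasets.load_ground_pattern()


@pytest.fixture(scope="session")
def sinensis_order():
    return datasets.sinensis_gene_order()


@pytest.fixture(scope="session")
def codon_table():
    return datasets.load_codon_table()


@pytest.fixture(scope="session")
def codon_counts():
    return datasets.load_codon_counts()


@pytest.fixture(scope="session")
def default_genome():
    """One full-size synthetic genome with its planted truth."""
    return generate_mitogenome(GenomeSpec(seed=101))
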