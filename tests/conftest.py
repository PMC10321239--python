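import pytest

from sua5kit.annotation import reference_pair
from sua5kit.records import ProteinRecord
from sua5kit.simulate import (
    SyntheticDatasetSpec,
    evolve_sequences,
    inject_hgt,
    make_reference_templates,
)


@pytest.fixture(scope="session")
def refs():
    return reference_pair()


@pytest.fixture(scope="session")
def sua5_template() -> ProteinRecord:
    return make_reference_templates()[0]


@pytest.fixture(scope="session")
def tsac_template() -> ProteinRecord:
    return make_reference_templates()[1]


@pytest.fixture(scope="session")
def small_dataset(sua5_template):
    """16 Sua5 sequences diverged on a balanced tree, moderate divergence."""
    spec = SyntheticDatasetSpec(n_taxa=16, subst_rate=0.05, indel_rate=0.1, seed=11)
    return evolve_sequences(sua5_template, spec)


@pytest.fixture(scope="session")
def hgt_dataset(sua5_template):
    """32-taxon dataset with 4 cross-phylum transfers at 2% copy noise."""
    spec = SyntheticDatasetSpec(n_taxa=32, subst_rate=0.05, indel_rate=0.1, seed=21)
    ds = evolve_sequences(sua5_template, spec)
    return inject_hgt(ds, 4, divergence_rank=1, seed=22, noise=0.02)
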