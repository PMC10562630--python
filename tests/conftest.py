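import dendropy
import pytest

from ampevo.curation import PeptideRecord
from ampevo.synthetic import SyntheticConfig, generate_peptides, simulate_species_tree


@pytest.fixture(scope="session")
def small_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def yule_tree_10() -> dendropy.Tree:
    return simulate_species_tree(10, seed=11)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def peptide_sets(default_config):
    return generate_peptides(default_config)


def make_peptide(seq: str, pid: str = "p1", **kwargs) -> PeptideRecord:
    return PeptideRecord(id=pid, sequence=seq, **kwargs)
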