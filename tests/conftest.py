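import dendropy
import pytest

from paleozyme import models, seqsim
from paleozyme.msa import Alignment


@pytest.fixture(scope="session")
def jtt():
    return models.jtt()


@pytest.fixture(scope="session")
def four_taxon_tree():
    """Rooted binary 4-taxon tree with fixed branch lengths and node labels."""
    tree = dendropy.Tree.get(
        data="((A:0.1,B:0.2)N1:0.15,(C:0.3,D:0.05)N2:0.1)N0;", schema="newick"
    )
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def four_taxon_alignment():
    return Alignment({"A": "ACDKR", "B": "ACEKR", "C": "GCDKW", "D": "ACD-R"})


@pytest.fixture(scope="session")
def small_family(jtt):
    """Simulated 6-taxon family at moderate divergence with a few indels."""
    tree = seqsim.sample_yule_tree(6, 2.0, 11)
    return seqsim.evolve_alignment(tree, 200, jtt, indel_rate=0.02, seed=23)
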