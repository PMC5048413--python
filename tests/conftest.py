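import numpy as np
import pytest

import altisel as al

STUDY_TREE = (
    "(out:0.4,(low_rana:0.1,high_rana:0.1 #1):0.15,"
    "(low_bufo:0.1,high_bufo:0.1):0.15);"
)


@pytest.fixture()
def study_tree() -> al.Phylogeny:
    """Five-taxon study topology with the high-altitude foreground."""
    return al.Phylogeny.from_newick(STUDY_TREE)


@pytest.fixture()
def small_tree() -> al.Phylogeny:
    return al.Phylogeny.from_newick("(a:0.2,b:0.3,c:0.25);")


@pytest.fixture(scope="session")
def m0_alignment():
    """One medium M0-simulated alignment shared across read-only tests."""
    tree = al.Phylogeny.from_newick(STUDY_TREE)
    params = al.SeqSimParams(
        tree=tree,
        kappa=2.0,
        omega_map={b: 0.2 for b in tree.branches},
        n_codons=300,
        seed=17,
    )
    aln, _ = al.simulate_codon_alignment(params)
    return aln, tree


def random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    from altisel._codons import SENSE_CODONS

    return "".join(rng.choice(SENSE_CODONS, size=n_codons))
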