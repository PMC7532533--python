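import numpy as np
import pytest

from phylodrivers.io_formats import GeneFamily, GeneTree, Msa, encode_residues
from phylodrivers.synthetic import SimulationConfig, simulate_family


def make_msa(rows: dict[str, str], reference_id: str) -> Msa:
    ids = list(rows)
    matrix = np.stack([encode_residues(rows[i]) for i in ids])
    return Msa(ids, matrix, reference_id)


@pytest.fixture
def caterpillar_tree() -> GeneTree:
    return GeneTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4_tree() -> GeneTree:
    return GeneTree.from_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture(scope="session")
def planted_family():
    """A seeded synthetic family with a planted compensated driver."""
    seed = 0
    while True:
        try:
            return simulate_family(SimulationConfig(seed=seed), plant_compensation=True)
        except ValueError:
            seed += 1


@pytest.fixture(scope="session")
def toy_family():
    """A tiny fully hand-specified gene family."""
    rows = {
        "HUMAN": "MKTAYV",
        "CHIMP": "MKTAYV",
        "FROG":  "MKTSYV",
        "FLY":   "MRTSYI",
        "YEAST": "MRTSFI",
        "PLANT": "MRTSFI",
    }
    msa = make_msa(rows, "HUMAN")
    tree = GeneTree.from_newick(
        "(((HUMAN:0.1,CHIMP:0.1):0.3,FROG:0.4):0.6,(FLY:0.7,(YEAST:0.5,PLANT:0.5):0.4):0.5);"
    )
    from phylodrivers.io_formats import TaxonAnnotation

    species = {s: s.lower() for s in rows}
    clade = {
        "HUMAN": "vertebrate", "CHIMP": "vertebrate", "FROG": "vertebrate",
        "FLY": "invertebrate", "YEAST": "fungus", "PLANT": "plant",
    }
    path = {s: ("cellular", clade[s], s.lower()) for s in rows}
    taxa = TaxonAnnotation(species, clade, path)
    return GeneFamily("TOY1", msa, tree, taxa)
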