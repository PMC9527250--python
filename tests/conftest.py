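import numpy as np
import pytest

from sedadna.qc import Read
from sedadna.taxonomy import ReferenceDB, ReferenceSequence, TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """Two-domain toy taxonomy with genus/species structure."""
    nodes = [
        TaxonNode(1, 1, "root", "root"),
        TaxonNode(2, 1, "domain", "Eukaryota"),
        TaxonNode(3, 1, "domain", "Bacteria"),
        TaxonNode(10, 2, "phylum", "Bacillariophyta"),
        TaxonNode(11, 10, "genus", "Chaetoceros"),
        TaxonNode(12, 11, "species", "Chaetoceros affinis"),
        TaxonNode(13, 11, "species", "Chaetoceros debilis"),
        TaxonNode(14, 10, "genus", "Fragilariopsis"),
        TaxonNode(15, 14, "species", "Fragilariopsis cylindrus"),
        TaxonNode(20, 2, "phylum", "Ascomycota"),
        TaxonNode(21, 20, "species", "Penicillium sp."),
        TaxonNode(30, 3, "phylum", "Cyanobacteria"),
        TaxonNode(31, 30, "species", "Synechococcus sp."),
    ]
    return TaxonomyTree(nodes)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def toy_refs(small_tree):
    """Random 300-bp marker references for the species of small_tree."""
    rng = np.random.default_rng(42)
    seqs = [
        ReferenceSequence(f"SSU_t{t}", t, "SSU", random_seq(rng, 300))
        for t in (12, 13, 15, 21, 31)
    ]
    return ReferenceDB(seqs, small_tree, k=12)


def make_read(seq: str, read_id: str = "r1", sample_id: str = "s1") -> Read:
    return Read(read_id, sample_id, seq)
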