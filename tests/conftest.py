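import io

import pytest

from sedmeta.hits import SubjectMeta
from sedmeta.ontology import FunctionOntology
from sedmeta.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture
def chain_tree() -> TaxonomyTree:
    """root -> A -> B plus root -> C (depths root:0, A:1, B:2, C:1)."""
    return TaxonomyTree(
        [
            TaxonNode("root", "root", "no rank", "root"),
            TaxonNode("A", "root", "phylum", "A"),
            TaxonNode("B", "A", "genus", "B"),
            TaxonNode("C", "root", "phylum", "C"),
        ]
    )


@pytest.fixture
def genus_tree() -> TaxonomyTree:
    """Two genera under one phylum, one genus in a second phylum.

        root -- P1 -- G1 -- s1, s2
                   \\- G2 -- s3
             \\- P2 -- G3 -- s4
    """
    return TaxonomyTree(
        [
            TaxonNode("root", "root", "no rank", "root"),
            TaxonNode("P1", "root", "phylum"),
            TaxonNode("P2", "root", "phylum"),
            TaxonNode("G1", "P1", "genus"),
            TaxonNode("G2", "P1", "genus"),
            TaxonNode("G3", "P2", "genus"),
            TaxonNode("s1", "G1", "species"),
            TaxonNode("s2", "G1", "species"),
            TaxonNode("s3", "G2", "species"),
            TaxonNode("s4", "G3", "species"),
        ]
    )


@pytest.fixture
def genus_meta() -> SubjectMeta:
    meta = SubjectMeta()
    meta.add("sub1", "s1", ["F1"])
    meta.add("sub2", "s2", ["F2"])
    meta.add("sub3", "s3", [])
    meta.add("sub4", "s4", ["F1", "F3"])
    return meta


@pytest.fixture
def small_ontology() -> FunctionOntology:
    onto = FunctionOntology()
    onto.add("F1", "role one", [("P1", "M1", "S1")])
    onto.add("F2", "role two", [("P1", "M1", "S2"), ("P1", "M2", "S3")])  # same level-1 parent twice
    onto.add("F3", "role three", [("P1", "M1", "S1"), ("Q1", "M3", "S4")])  # two level-1 parents
    return onto


def hit_line(q="q1", s="s1", bits=60.0) -> str:
    return f"{q}\t{s}\t90.00\t100\t10\t0\t1\t100\t1\t100\t1e-20\t{bits}"


def make_hits_stream(lines) -> io.StringIO:
    return io.StringIO("\n".join(lines) + "\n")
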