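"""GO-annotation semantic similarity and protein-complex reliability scoring."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import dignifi as dg

from conftest import random_connected_network


def make_annot(**gene_terms):
    return dg.GOAnnotationSet({g: set(ts) for g, ts in gene_terms.items()})


@pytest.fixture
def corpus():
    """Two genes sharing a 2-gene term; a 100-gene term sets S_max."""
    mapping = {"A": {"SPECIFIC", "HUGE"}, "B": {"SPECIFIC", "HUGE"}}
    for i in range(98):
        mapping[f"G{i}"] = {"HUGE"}
    return dg.GOAnnotationSet(mapping)


class TestGOSimilarity:
    def test_specific_shared_term(self, corpus):
        assert corpus.s_max == 100
        assert dg.go_similarity(corpus, "A", "B") == pytest.approx(math.log(50), abs=1e-12)

    def test_most_general_term_carries_no_information(self, corpus):
        # A and G0 share only the S_max-sized term
        assert dg.go_similarity(corpus, "A", "G0") == 0.0

    def test_no_shared_terms(self):
        annot = make_annot(A={"T1"}, B={"T2"})
        assert dg.go_similarity(annot, "A", "B") == 0.0

    def test_unknown_gene_scores_zero(self, corpus):
        assert dg.go_similarity(corpus, "A", "UNANNOTATED") == 0.0

    def test_symmetric_and_nonnegative(self, corpus):
        genes = ["A", "B", "G0", "G1"]
        for u, v in itertools.combinations(genes, 2):
            s = dg.go_similarity(corpus, u, v)
            assert s >= 0.0
            assert s == dg.go_similarity(corpus, v, u)

    def test_log_base_rescales(self, corpus):
        natural = dg.go_similarity(corpus, "A", "B")
        base2 = dg.go_similarity(corpus, "A", "B", log_base=2)
        assert base2 == pytest.approx(natural / math.log(2), abs=1e-12)

    def test_growing_minimal_term_lowers_similarity(self):
        # information-content monotonicity in the shared-term size
        scores = []
        for size in (2, 5, 20):
            mapping = {f"X{i}": {"SHARED"} for i in range(size - 2)}
            mapping.update(A={"SHARED"}, B={"SHARED"})
            mapping.update({f"PAD{i}": {"BIG"} for i in range(50)})
            scores.append(dg.go_similarity(dg.GOAnnotationSet(mapping), "A", "B"))
        assert scores[0] > scores[1] > scores[2]

    def test_ancestor_propagation_optional(self):
        ancestors = {"CHILD": {"PARENT"}}
        plain = dg.GOAnnotationSet({"A": {"CHILD"}, "B": {"PARENT"}})
        assert dg.go_similarity(plain, "A", "B") == 0.0
        propagated = dg.GOAnnotationSet({"A": {"CHILD"}, "B": {"PARENT"}},
                                        ancestors=ancestors)
        assert "PARENT" in propagated.terms("A")


class TestGAFReader:
    GAF = (
        "!gaf-version: 2.2\n"
        "UniProtKB\tP1\tGENEA\t\tGO:0001\tPMID:1\tIDA\t\tP\tdesc\t\tprotein\ttaxon:9606\t20200101\tUniProt\t\t\n"
        "UniProtKB\tP1\tGENEA\t\tGO:0002\tPMID:1\tIEA\t\tF\tdesc\t\tprotein\ttaxon:9606\t20200101\tUniProt\t\t\n"
        "UniProtKB\tP2\tGENEB\tNOT\tGO:0001\tPMID:1\tIDA\t\tP\tdesc\t\tprotein\ttaxon:9606\t20200101\tUniProt\t\t\n"
        "UniProtKB\tP3\tGENEC\t\tGO:0001\tPMID:2\tISS\t\tC\tdesc\t\tprotein\ttaxon:9606\t20200101\tUniProt\t\t\n"
    )

    def test_parses_symbols_terms_and_not_qualifier(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(self.GAF)
        annot = dg.read_gaf(p)
        assert annot.terms("GENEA") == {"GO:0001", "GO:0002"}
        assert "GENEB" not in annot  # NOT-qualified row skipped
        assert annot.term_sizes["GO:0001"] == 2

    def test_exclude_iea(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(self.GAF)
        annot = dg.read_gaf(p, exclude_iea=True)
        assert annot.terms("GENEA") == {"GO:0001"}

    def test_simplified_tsv_reader(self, tmp_path):
        p = tmp_path / "annot.tsv"
        p.write_text("A\tGO:1\nA\tGO:2\nB\tGO:1\n")
        annot = dg.read_annotation_tsv(p)
        assert annot.terms("A") == {"GO:1", "GO:2"}
        assert annot.term_sizes["GO:1"] == 2


class TestComplexScore:
    def test_isolated_triangle_scores_one(self, toys):
        assert dg.complex_score(toys["triangle"], {"A", "B", "C"}) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_boundary_edge_dilutes_score(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A"), ("A", "X")], weight=1.0)
        net = dg.Network(g)
        assert dg.complex_score(net, {"A", "B", "C"}) == pytest.approx(0.75, abs=1e-12)

    def test_two_members_without_edge_score_zero(self, toys):
        net = toys["two disconnected triangles"]
        assert dg.complex_score(net, {"A", "X"}) == 0.0

    def test_fewer_than_two_present_members_score_zero(self, toys):
        net = toys["triangle"]
        assert dg.complex_score(net, {"A"}) == 0.0
        assert dg.complex_score(net, {"ABSENT1", "ABSENT2"}) == 0.0

    def test_absent_members_ignored_in_density(self, toys):
        # triangle + one off-network member: density over 3 present nodes
        assert dg.complex_score(toys["triangle"], {"A", "B", "C", "GHOST"}) == pytest.approx(1.0)

    def test_score_bounded_on_binary_networks(self, rng):
        for _ in range(10):
            net = random_connected_network(rng, n_max=25)
            members = set(rng.choice(net.nodes, size=5, replace=False))
            assert 0.0 <= dg.complex_score(net, members) <= 1.0

    def test_score_one_iff_isolated_clique(self, toys):
        star = toys["five-leaf star"]
        assert dg.complex_score(star, {"HUB", "A", "B"}) < 1.0  # boundary edges exist


class TestComplexSimilarity:
    def test_single_shared_isolated_triangle(self, toys):
        catalog = dg.ComplexCatalog.from_mapping({"C1": {"A", "B", "C"}})
        assert dg.complex_similarity(catalog, toys["triangle"], "A", "B") == pytest.approx(1.0)

    def test_no_shared_complex(self, toys):
        catalog = dg.ComplexCatalog.from_mapping({"C1": {"A", "B"}, "C2": {"B", "C"}})
        assert dg.complex_similarity(catalog, toys["triangle"], "A", "C") == 0.0

    def test_additive_over_shared_complexes(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A"), ("A", "X")], weight=1.0)
        net = dg.Network(g)
        catalog = dg.ComplexCatalog.from_mapping(
            {"ISOLATED": {"B", "C", "A"}, "DILUTED": {"A", "B", "C"}}
        )
        # identical membership, but scored independently: 0.75 + 0.75
        got = dg.complex_similarity(catalog, net, "B", "C")
        assert got == pytest.approx(1.5, abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            net = random_connected_network(rng, n_max=20)
            genes = list(net.nodes)
            mapping = {
                f"C{i}": set(rng.choice(genes, size=int(rng.integers(2, 6)), replace=False))
                for i in range(6)
            }
            catalog = dg.ComplexCatalog.from_mapping(mapping)
            scores = {cid: dg.complex_score(net, mem) for cid, mem in mapping.items()}
            for u, v in [(genes[0], genes[1]), (genes[1], genes[2])]:
                expected = sum(s for cid, s in scores.items()
                               if u in mapping[cid] and v in mapping[cid])
                assert dg.complex_similarity(catalog, net, u, v) == pytest.approx(expected)
            for u, v in [(genes[0], genes[1])]:
                assert dg.complex_similarity(catalog, net, u, v) == dg.complex_similarity(
                    catalog, net, v, u
                )

    def test_complex_catalog_reader(self, tmp_path):
        p = tmp_path / "cpx.tsv"
        p.write_text("C1\tA;B;C\nC2\tX;Y\n")
        catalog = dg.read_complexes(p)
        assert len(catalog) == 2
        assert set(catalog.complexes_of("A")) == {"C1"}
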