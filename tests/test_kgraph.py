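"""Knowledge graph: extraction, fusion, query, density, chains."""

import pytest

from epiedu import kgraph as kg
from epiedu.errors import ValidationError
from epiedu.textprep import EntityMention

PATTERN = kg.RelationPattern(
    "virus", frozenset({"经"}), "transmission_mode",
    "transmission_pathway", window=3)


def _doc(bid, tokens, spans):
    mentions = [EntityMention(bid, s, e, c) for s, e, c in spans]
    return kg.TaggedDoc(bid, tokens, mentions)


def transmission_doc(bid="b1"):
    return _doc(bid, ["奥密克戎", "经", "空气传播"],
                [(0, 1, "virus"), (2, 3, "transmission_mode")])


class TestExtract:
    def test_trigger_pattern_emits_edge(self):
        graph = kg.extract_relations([transmission_doc()], [PATTERN])
        assert graph.edges() == [
            ("奥密克戎", "transmission_pathway", "空气传播", 1)]

    def test_no_trigger_no_edge(self):
        doc = _doc("b1", ["奥密克戎", "和", "空气传播"],
                   [(0, 1, "virus"), (2, 3, "transmission_mode")])
        graph = kg.extract_relations([doc], [PATTERN])
        assert graph.n_edges == 0

    def test_evidence_aggregates_across_corpus(self):
        docs = [transmission_doc(f"b{i}") for i in range(3)]
        graph = kg.extract_relations(docs, [PATTERN])
        assert graph.edges() == [
            ("奥密克戎", "transmission_pathway", "空气传播", 3)]

    def test_unknown_category_rejected(self):
        bad = kg.RelationPattern("martian", frozenset(), "virus",
                                 "transmission_pathway")
        with pytest.raises(ValidationError):
            kg.extract_relations([transmission_doc()], [bad])


def toy_graph():
    g = kg.KnowledgeGraph()
    g.add_node("NCP", "virus")
    g.add_node("COVID-19", "virus")
    g.add_node("mask-wearing", "preventive_measure")
    g.add_edge("NCP", "preventive_measure", "mask-wearing",
               evidence=2, bulletins=["b1", "b2"])
    g.add_edge("COVID-19", "preventive_measure", "mask-wearing",
               evidence=3, bulletins=["b2", "b3", "b4"])
    return g


class TestFuse:
    def test_synonyms_merge_with_alias(self):
        fused = kg.fuse(toy_graph(), {"NCP": "COVID-19"})
        assert "NCP" not in fused.g.nodes
        assert "NCP" in fused.aliases("COVID-19")

    def test_parallel_edge_evidence_sums(self):
        fused = kg.fuse(toy_graph(), {"NCP": "COVID-19"})
        assert fused.edges() == [
            ("COVID-19", "preventive_measure", "mask-wearing", 5)]

    def test_no_synonyms_is_identity(self):
        g = toy_graph()
        fused = kg.fuse(g, {})
        assert fused.edges() == g.edges()
        assert set(fused.g.nodes) == set(g.g.nodes)

    def test_evidence_mass_conserved(self):
        g = toy_graph()
        fused = kg.fuse(g, {"NCP": "COVID-19"})
        assert fused.total_evidence() == g.total_evidence()

    def test_synonym_cycle_rejected(self):
        with pytest.raises(ValidationError):
            kg.fuse(toy_graph(), {"NCP": "COVID-19", "COVID-19": "NCP"})

    def test_chained_synonyms_resolve(self):
        g = toy_graph()
        g.add_node("2019-nCoV", "virus")
        fused = kg.fuse(g, {"2019-nCoV": "NCP", "NCP": "COVID-19"})
        assert fused.aliases("COVID-19") >= {"NCP", "2019-nCoV"}


def table_style_graph():
    g = kg.KnowledgeGraph()
    g.add_node("Omicron", "virus")
    g.add_node("airborne transmission", "transmission_mode")
    g.add_node("mask-wearing", "preventive_measure")
    g.add_node("Lianhua Qingwen", "drug")
    g.add_edge("Omicron", "transmission_pathway", "airborne transmission",
               bulletins=["b1", "b2", "b3", "b4"])
    g.add_edge("Omicron", "preventive_measure", "mask-wearing",
               bulletins=["b1", "b2", "b5"])
    return g


class TestQuery:
    def test_typed_pattern_binds(self):
        res = kg.query(table_style_graph(),
                       ("virus", "transmission_pathway", None))
        assert ("Omicron", "transmission_pathway",
                "airborne transmission") in res

    def test_full_wildcard_returns_all_edges(self):
        g = table_style_graph()
        assert len(kg.query(g, (None, None, None))) == g.n_edges

    def test_no_match_is_empty(self):
        assert kg.query(table_style_graph(),
                        ("drug", "therapeutic_drug", None)) == []

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            kg.query(table_style_graph(), ("martian", None, None))
        with pytest.raises(ValidationError):
            kg.query(table_style_graph(), (None, "befriends", None))

    def test_results_stable_across_runs(self):
        g = table_style_graph()
        assert kg.query(g, (None, None, None)) == \
            kg.query(g, (None, None, None))


class TestDensity:
    def _complete3(self):
        g = kg.KnowledgeGraph()
        for n in "abc":
            g.add_node(n, "virus")
        for u in "abc":
            for v in "abc":
                if u != v:
                    g.add_edge(u, "transmission_pathway", v)
        return g

    def test_complete_digraph_density_one(self):
        assert kg.subgraph_density(self._complete3(), {"virus"}) == 1.0

    def test_partial_density(self):
        g = kg.KnowledgeGraph()
        for n in "abc":
            g.add_node(n, "virus")
        g.add_edge("a", "transmission_pathway", "b")
        g.add_edge("b", "transmission_pathway", "c")
        assert kg.subgraph_density(g, {"virus"}) == pytest.approx(1 / 3)

    def test_empty_induced_edges_zero(self):
        g = kg.KnowledgeGraph()
        g.add_node("a", "virus")
        g.add_node("b", "virus")
        assert kg.subgraph_density(g, {"virus"}) == 0.0

    def test_too_few_nodes_rejected(self):
        g = kg.KnowledgeGraph()
        g.add_node("a", "virus")
        with pytest.raises(ValidationError):
            kg.subgraph_density(g, {"virus"})

    def test_monotone_in_edges(self):
        g = kg.KnowledgeGraph()
        for n in "abcd":
            g.add_node(n, "virus")
        last = 0.0
        for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]:
            g.add_edge(u, "transmission_pathway", v)
            d = kg.subgraph_density(g, {"virus"})
            assert d >= last
            last = d


class TestChains:
    def _chain_graph(self):
        g = kg.KnowledgeGraph()
        g.add_node("Omicron", "virus")
        g.add_node("airborne", "transmission_mode")
        g.add_node("mask-wearing", "preventive_measure")
        docs_ab = [f"b{i}" for i in range(10)]
        docs_bc = [f"b{i}" for i in range(4)] + ["b97", "b98"]
        g.add_edge("Omicron", "transmission_pathway", "airborne",
                   evidence=len(docs_ab), bulletins=docs_ab)
        g.add_edge("airborne", "preventive_measure", "mask-wearing",
                   evidence=len(docs_bc), bulletins=docs_bc)
        return g

    def test_joint_instantiation_count(self):
        chain = ["Omicron", "transmission_pathway", "airborne",
                 "preventive_measure", "mask-wearing"]
        assert kg.chain_frequency(self._chain_graph(), chain) == 4

    def test_absent_node_gives_zero(self):
        chain = ["XE", "transmission_pathway", "airborne"]
        assert kg.chain_frequency(self._chain_graph(), chain) == 0

    def test_single_edge_chain_equals_bulletin_support(self):
        g = self._chain_graph()
        chain = ["Omicron", "transmission_pathway", "airborne"]
        assert kg.chain_frequency(g, chain) == 10


class TestAssociationStrength:
    DOCS = (
        [["a", "b"]] * 4 + [["a"]] * 6 + [["b"]] * 4 + [["c"]] * 6
    )  # a:10, b:8, both:4, n=20

    def test_overlap_coefficient(self):
        assert kg.association_strength(self.DOCS, "a", "b") == \
            pytest.approx(0.4)

    def test_symmetric(self):
        assert kg.association_strength(self.DOCS, "a", "b") == \
            kg.association_strength(self.DOCS, "b", "a")

    def test_always_cooccur_is_one(self):
        docs = [["x", "y"], ["y", "x", "z"]]
        assert kg.association_strength(docs, "x", "y") == 1.0

    def test_never_cooccur_is_zero(self):
        assert kg.association_strength(self.DOCS, "a", "c") == 0.0

    def test_absent_term_rejected(self):
        with pytest.raises(ValidationError):
            kg.association_strength(self.DOCS, "a", "zz")


class TestExportRoundTrip:
    def test_node_link_round_trip(self):
        g = table_style_graph()
        back = kg.KnowledgeGraph.from_node_link(g.to_node_link())
        assert back.edges() == g.edges()
        assert set(back.g.nodes) == set(g.g.nodes)
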