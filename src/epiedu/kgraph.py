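"""Epidemic knowledge graph: pattern-based relation extraction, fusion of
synonymous entities, triple-pattern querying, and graph statistics.

Nodes are typed entities (virus, symptom, preventive measure, ...); edges are
typed directed relations (transmission pathway, preventive measure, ...) that
carry an evidence count and bulletin-level provenance, so knowledge chains
can be counted in bulletin occurrences.  Storage is an in-memory
``networkx.MultiDiGraph`` keyed by canonical name with the relation as the
edge key; retrieval is a triple-pattern API (type?, relation?, type?) rather
than a query-language parser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .textprep import EntityMention

NODE_TYPES = frozenset({
    "virus", "symptom", "preventive_measure", "medical_institution",
    "vaccine_type", "drug", "location", "temporal", "transmission_mode",
})

RELATIONS = frozenset({
    "transmission_pathway", "preventive_measure", "therapeutic_drug",
    "geographical_location", "vaccination_schedule",
})

#: entity-tagger categories -> graph node types
CATEGORY_TO_NODE_TYPE = {
    "virus": "virus",
    "symptom": "symptom",
    "drug": "drug",
    "preventive_measure": "preventive_measure",
    "institution": "medical_institution",
    "location": "location",
    "temporal": "temporal",
    "transmission_mode": "transmission_mode",
    "vaccine_type": "vaccine_type",
}


@dataclass(frozen=True)
class RelationPattern:
    """(source category, trigger tokens, target category, relation, window).

    Matches a source mention followed by a target mention whose start is at
    most ``window`` tokens past the source's end, with at least one trigger
    token strictly between them (an empty trigger set means plain proximity).
    """

    source_category: str
    triggers: frozenset
    target_category: str
    relation: str
    window: int = 5

    def validate(self, known_categories: set[str]) -> None:
        for cat in (self.source_category, self.target_category):
            if cat not in known_categories:
                raise ValidationError(f"unknown category {cat!r} in pattern")
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")
        if self.window < 0:
            raise ValidationError("window must be non-negative")


class KnowledgeGraph:
    """Typed property graph with alias tracking and edge provenance."""

    def __init__(self):
        self.g = nx.MultiDiGraph()
        self.fusion_report: dict = {}

    # -- construction -------------------------------------------------
    def add_node(self, name: str, node_type: str,
                 aliases: Iterable[str] = ()) -> None:
        if node_type not in NODE_TYPES:
            raise ValidationError(f"unknown node type {node_type!r}")
        if name in self.g:
            types = self.g.nodes[name].setdefault("types", {node_type})
            types.add(node_type)
            self.g.nodes[name]["aliases"].update(aliases)
        else:
            self.g.add_node(name, node_type=node_type, types={node_type},
                            aliases=set(aliases))

    def add_edge(self, source: str, relation: str, target: str,
                 evidence: int = 1, bulletins: Iterable[str] = ()) -> None:
        if relation not in RELATIONS:
            raise ValidationError(f"unknown relation {relation!r}")
        if source == target:
            raise ValidationError("self-loops are not allowed")
        for name in (source, target):
            if name not in self.g:
                raise ValidationError(f"edge endpoint {name!r} not in graph")
        if evidence < 1:
            raise ValidationError("evidence_count must be >= 1")
        if self.g.has_edge(source, target, key=relation):
            data = self.g[source][target][relation]
            data["evidence"] += evidence
            data["bulletins"].update(bulletins)
        else:
            self.g.add_edge(source, target, key=relation,
                            evidence=evidence, bulletins=set(bulletins))

    # -- views --------------------------------------------------------
    def node_type(self, name: str) -> str:
        return self.g.nodes[name]["node_type"]

    def aliases(self, name: str) -> set[str]:
        return self.g.nodes[name]["aliases"]

    def edges(self) -> list[tuple[str, str, str, int]]:
        return sorted(
            (u, k, v, d["evidence"])
            for u, v, k, d in self.g.edges(keys=True, data=True))

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def total_evidence(self) -> int:
        return sum(d["evidence"] for _, _, d in self.g.edges(data=True))

    def known_surfaces(self) -> set[str]:
        out = set()
        for n, data in self.g.nodes(data=True):
            out.add(n)
            out.update(data["aliases"])
        return out

    # -- export -------------------------------------------------------
    def to_node_link(self) -> dict:
        data = nx.node_link_data(self.g, edges="links")
        for nd in data["nodes"]:
            nd["aliases"] = sorted(nd.get("aliases", ()))
            nd["types"] = sorted(nd.get("types", ()))
        for e in data["links"]:
            e["bulletins"] = sorted(e.get("bulletins", ()))
        return data

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_node_link(), fh, ensure_ascii=False,
                      sort_keys=True, indent=1)

    @classmethod
    def from_node_link(cls, data: dict) -> "KnowledgeGraph":
        kg = cls()
        for nd in data["nodes"]:
            kg.add_node(nd["id"], nd["node_type"], nd.get("aliases", ()))
        for e in data["links"]:
            kg.add_edge(e["source"], e["key"], e["target"],
                        evidence=e.get("evidence", 1),
                        bulletins=e.get("bulletins", ()))
        return kg

    def write_graphml(self, path) -> None:
        g2 = nx.MultiDiGraph()
        for n, d in self.g.nodes(data=True):
            g2.add_node(n, node_type=d["node_type"],
                        aliases=";".join(sorted(d["aliases"])))
        for u, v, k, d in self.g.edges(keys=True, data=True):
            g2.add_edge(u, v, key=k, relation=k, evidence=d["evidence"],
                        bulletins=";".join(sorted(d["bulletins"])))
        nx.write_graphml(g2, path)


@dataclass
class TaggedDoc:
    """A bulletin's tokens plus its entity mentions (input to extraction)."""

    bulletin_id: str
    tokens: Sequence[str]
    mentions: Sequence[EntityMention]


def extract_relations(
    tagged_docs: Iterable[TaggedDoc],
    patterns: Sequence[RelationPattern],
    category_types: dict[str, str] | None = None,
) -> KnowledgeGraph:
    """Build a graph by matching trigger patterns between entity mentions."""
    cat_types = dict(CATEGORY_TO_NODE_TYPE)
    if category_types:
        cat_types.update(category_types)
    for p in patterns:
        p.validate(set(cat_types))

    kg = KnowledgeGraph()
    for doc in tagged_docs:
        toks = list(doc.tokens)
        mentions = sorted(doc.mentions, key=lambda m: (m.start, m.end))
        for p in patterns:
            for src in mentions:
                if src.category != p.source_category:
                    continue
                for tgt in mentions:
                    if tgt.category != p.target_category or tgt is src:
                        continue
                    gap = tgt.start - src.end
                    if gap < 0 or gap > p.window:
                        continue
                    between = toks[src.end:tgt.start]
                    if p.triggers and not (p.triggers & set(between)):
                        continue
                    s_name = " ".join(toks[src.start:src.end])
                    t_name = " ".join(toks[tgt.start:tgt.end])
                    if s_name == t_name:
                        continue
                    kg.add_node(s_name, cat_types[src.category])
                    kg.add_node(t_name, cat_types[tgt.category])
                    kg.add_edge(s_name, p.relation, t_name,
                                evidence=1, bulletins=[doc.bulletin_id])
    return kg


def _resolve_canonical(synonyms: dict[str, str]) -> dict[str, str]:
    """Follow alias chains to a fixed point, rejecting cycles."""
    out = {}
    for alias in synonyms:
        cur = alias
        seen = {cur}
        while cur in synonyms:
            cur = synonyms[cur]
            if cur in seen:
                raise ValidationError(
                    f"synonym cycle involving {alias!r}")
            seen.add(cur)
        out[alias] = cur
    return out


def fuse(
    graph: KnowledgeGraph,
    synonym_table: dict[str, str] | None = None,
    disambiguation_rules: dict[tuple[str, str], str] | None = None,
    doc_tokens: dict[str, Sequence[str]] | None = None,
) -> KnowledgeGraph:
    """Merge synonymous nodes and resolve ambiguous surfaces.

    Merged nodes union their aliases and re-point their edges; parallel
    edges sum their evidence counts (total evidence mass is conserved).
    Surfaces carrying more than one type are resolved through
    ``disambiguation_rules`` ((surface, context token) -> category, matched
    against the tokens of provenance bulletins when ``doc_tokens`` is
    given); unresolved surfaces are flagged in ``fusion_report``.
    """
    synonyms = _resolve_canonical(dict(synonym_table or {}))
    mapping = {n: synonyms.get(n, n) for n in graph.g.nodes}

    fused = KnowledgeGraph()
    unresolved: list[str] = []
    for name, data in sorted(graph.g.nodes(data=True)):
        canon = mapping[name]
        types = set(data["types"])
        node_type = data["node_type"]
        if len(types) > 1:
            resolved = None
            if disambiguation_rules:
                ctx_tokens: set[str] = set()
                if doc_tokens:
                    for _, _, d in graph.g.edges(name, data=True):
                        for bid in d["bulletins"]:
                            ctx_tokens.update(doc_tokens.get(bid, ()))
                for (surface, ctx), cat in sorted(disambiguation_rules.items()):
                    if surface == name and (ctx is None or ctx in ctx_tokens):
                        resolved = cat
                        break
            if resolved is not None:
                node_type = CATEGORY_TO_NODE_TYPE.get(resolved, resolved)
            else:
                unresolved.append(name)
        fused.add_node(canon, node_type)
        if canon != name:
            fused.g.nodes[canon]["aliases"].add(name)
        fused.g.nodes[canon]["aliases"].update(
            a for a in data["aliases"] if a != canon)

    for u, v, k, d in graph.g.edges(keys=True, data=True):
        cu, cv = mapping[u], mapping[v]
        if cu == cv:
            continue  # merging collapsed this edge into a self-loop; drop
        fused.add_edge(cu, k, cv, evidence=d["evidence"],
                       bulletins=d["bulletins"])

    fused.fusion_report = {
        "merged": sorted(a for a, c in mapping.items() if a != c),
        "unresolved_ambiguous": sorted(unresolved),
    }
    return fused


def query(
    graph: KnowledgeGraph,
    pattern: tuple[str | None, str | None, str | None],
) -> list[tuple[str, str, str]]:
    """All (source, relation, target) bindings of a partially specified
    triple pattern; wildcards are None; results sorted by names."""
    src_t, rel, tgt_t = pattern
    for t in (src_t, tgt_t):
        if t is not None and t not in NODE_TYPES:
            raise ValidationError(f"unknown node type {t!r}")
    if rel is not None and rel not in RELATIONS:
        raise ValidationError(f"unknown relation {rel!r}")
    out = []
    for u, v, k in graph.g.edges(keys=True):
        if rel is not None and k != rel:
            continue
        if src_t is not None and graph.node_type(u) != src_t:
            continue
        if tgt_t is not None and graph.node_type(v) != tgt_t:
            continue
        out.append((u, k, v))
    return sorted(out)


def subgraph_density(graph: KnowledgeGraph, node_types: set[str]) -> float:
    """Directed density E/(V(V-1)) of the subgraph induced by node types;
    parallel edges between a pair count once."""
    for t in node_types:
        if t not in NODE_TYPES:
            raise ValidationError(f"unknown node type {t!r}")
    nodes = [n for n in graph.g.nodes if graph.node_type(n) in node_types]
    if len(nodes) < 2:
        raise ValidationError("need at least two nodes of the requested types")
    node_set = set(nodes)
    pairs = {
        (u, v) for u, v in graph.g.edges(nodes)
        if u in node_set and v in node_set
    }
    v = len(nodes)
    return len(pairs) / (v * (v - 1))


def chain_frequency(graph: KnowledgeGraph, chain: Sequence[str]) -> int:
    """Number of bulletins whose extracted edges jointly instantiate the
    full chain ``[node, relation, node, relation, node, ...]``."""
    if len(chain) < 3 or len(chain) % 2 == 0:
        raise ValidationError(
            "chain must alternate node/relation/node (>= 2 nodes)")
    support: set[str] | None = None
    for i in range(0, len(chain) - 2, 2):
        u, rel, v = chain[i], chain[i + 1], chain[i + 2]
        if not graph.g.has_edge(u, v, key=rel):
            return 0
        bulletins = graph.g[u][v][rel]["bulletins"]
        support = set(bulletins) if support is None else support & bulletins
    return len(support or ())


def association_strength(
    docs: Iterable[Iterable[str]], term_a: str, term_b: str
) -> float:
    """Overlap coefficient: P(a and b in bulletin) / max(P(a), P(b))."""
    n_a = n_b = n_ab = 0
    for doc in docs:
        s = set(doc)
        a, b = term_a in s, term_b in s
        n_a += a
        n_b += b
        n_ab += a and b
    if n_a == 0 or n_b == 0:
        missing = term_a if n_a == 0 else term_b
        raise ValidationError(f"term {missing!r} absent from the corpus")
    return n_ab / max(n_a, n_b)
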