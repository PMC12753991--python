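"""Rule engine that assembles personalized multimodal health-education
resources from mined knowledge elements.

Three deterministic mappings, all driven by a declarative YAML rule base:

* ``adapt_modality`` — user profile -> ordered resource formats (older
  adults get audio narration with large-font text; low-education users get
  short video with infographics; everyone else interactive Q&A with
  long-form text).  Topic-specific rules outrank these demographic
  defaults, so a virology topic for a 60+ user yields video + audio
  narration instead.
* ``map_content`` — topics/entities/rules -> framework sections, knowledge
  cards (with mandatory source citation and timeliness), risk alerts, and
  link-outs, each carrying the knowledge element and rule that produced it.
* ``detect_and_update`` — an unseen entity in a bulletin triggers the
  five-stage knowledge-update pipeline (recognition, source retrieval,
  triple generation, graph update, brief release).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources as _res
from typing import Iterable, Sequence

import yaml

from .assocmine import AssocRule
from .errors import ValidationError
from .kgraph import CATEGORY_TO_NODE_TYPE, KnowledgeGraph, TaggedDoc
from .synthcorpus import TOPICS

AGE_BANDS = ("18-30", "31-59", "60+")
EDUCATION_LEVELS = (
    "below_high_school", "high_school", "college", "postgraduate")

UPDATE_STAGES = (
    "recognition", "source_retrieval", "triple_generation",
    "graph_update", "brief_release",
)

#: node type of a co-mentioned entity -> relation used for generated triples
_TRIPLE_RELATION = {
    "transmission_mode": "transmission_pathway",
    "preventive_measure": "preventive_measure",
    "drug": "therapeutic_drug",
    "location": "geographical_location",
    "vaccine_type": "vaccination_schedule",
}


def age_band(age_years: int) -> str:
    if age_years >= 60:
        return "60+"
    if age_years >= 31:
        return "31-59"
    return "18-30"


@dataclass
class UserProfile:
    age_years: int
    education: str
    ehl_group: str = "medium_low"

    def __post_init__(self):
        if self.education not in EDUCATION_LEVELS:
            raise ValidationError(f"unknown education {self.education!r}")
        if self.ehl_group not in ("high", "medium_low"):
            raise ValidationError(f"unknown ehl_group {self.ehl_group!r}")

    @property
    def age_band(self) -> str:
        return age_band(self.age_years)


@dataclass
class ContentElement:
    kind: str  # knowledge_card | risk_alert | framework_section | link_out | comparative_chart
    text: str
    knowledge_element: str  # the topic/entity/rule that produced it
    rule_id: str
    source_citation: str = ""
    timeliness: str = ""

    def __post_init__(self):
        if self.kind == "knowledge_card":
            if not self.source_citation or not self.timeliness:
                raise ValidationError(
                    "knowledge cards require source citation and timeliness")


@dataclass
class ResourceSpec:
    formats: list[str]
    content_elements: list[ContentElement]
    provenance: list[str]  # rule ids that fired, in firing order

    def __post_init__(self):
        if not self.formats:
            raise ValidationError("formats must be non-empty")


@dataclass
class UpdateEvent:
    new_entity: str
    pipeline_stages: list[str]
    resulting_triples: list[tuple[str, str, str]]
    brief: str


def load_rule_base(path=None) -> dict:
    """Load a YAML rule base; the packaged default when no path is given."""
    if path is None:
        text = (_res.files("epiedu") / "data" / "default_rules.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    base = yaml.safe_load(text)
    for key in ("modality_rules", "content_rules", "frameworks"):
        if key not in base:
            raise ValidationError(f"rule base missing section {key!r}")
    return base


_DEFAULT_BASE: dict | None = None


def default_rule_base() -> dict:
    global _DEFAULT_BASE
    if _DEFAULT_BASE is None:
        _DEFAULT_BASE = load_rule_base()
    return _DEFAULT_BASE


def _modality_match(when: dict, profile: UserProfile,
                    topic_label: str | None) -> bool:
    if "topic" in when and when["topic"] != topic_label:
        return False
    if "min_age" in when and profile.age_years < when["min_age"]:
        return False
    if "max_age" in when and profile.age_years > when["max_age"]:
        return False
    if "education" in when and profile.education != when["education"]:
        return False
    return True


def _select_modality(profile: UserProfile, topic_label: str | None,
                     base: dict) -> tuple[list[str], str]:
    rules = sorted(base["modality_rules"],
                   key=lambda r: (-r.get("priority", 0), r["id"]))
    for rule in rules:
        if _modality_match(rule.get("when", {}), profile, topic_label):
            return list(rule["formats"]), rule["id"]
    raise ValidationError("no modality rule matched (rule base lacks default)")


def adapt_modality(profile: UserProfile, rule_base: dict | None = None) -> list[str]:
    """Demographic format defaults (no topic context)."""
    base = rule_base or default_rule_base()
    formats, _ = _select_modality(profile, None, base)
    return formats


def _rule_items(rules: Iterable[AssocRule]) -> set[str]:
    out: set[str] = set()
    for r in rules:
        out |= set(r.antecedent) | set(r.consequent)
    return out


def map_content(
    topic_label: str,
    entities: Sequence[str],
    rules: Sequence[AssocRule],
    kgraph: KnowledgeGraph | None = None,
    rule_base: dict | None = None,
    source_date: str = "2024-12-31",
) -> list[ContentElement]:
    """Map mined knowledge elements to structured content elements."""
    base = rule_base or default_rule_base()
    if topic_label not in TOPICS:
        raise ValidationError(f"unknown topic label {topic_label!r}")
    citation = base.get("default_citation",
                        "Source: National Health Commission bulletin")
    elements: list[ContentElement] = []
    for section in base["frameworks"].get(topic_label, []):
        elements.append(ContentElement(
            kind="framework_section", text=section.replace("_", " ").title(),
            knowledge_element=topic_label,
            rule_id=f"framework:{topic_label}"))

    entity_set = set(entities)
    items = _rule_items(rules)
    for rule in base["content_rules"]:
        fired = False
        element_key = ""
        if "when_entity" in rule:
            fired = rule["when_entity"] in entity_set
            element_key = rule["when_entity"]
        elif "when_rule_item" in rule:
            fired = rule["when_rule_item"] in items
            element_key = rule["when_rule_item"]
        elif "when_items_present" in rule:
            present = set(rule.get("when_items_present", ()))
            absent = set(rule.get("when_items_absent", ()))
            fired = present <= items and not (absent & items)
            element_key = "+".join(sorted(present))
        if not fired:
            continue
        kwargs = {}
        if rule["kind"] == "knowledge_card":
            kwargs = {"source_citation": citation, "timeliness": source_date}
        elements.append(ContentElement(
            kind=rule["kind"],
            text=rule.get("card_text") or rule.get("text", ""),
            knowledge_element=element_key,
            rule_id=rule["id"], **kwargs))
    return elements


def generate_resource(
    topic_label: str,
    entities: Sequence[str],
    rules: Sequence[AssocRule],
    profile: UserProfile,
    kgraph: KnowledgeGraph | None = None,
    rule_base: dict | None = None,
    source_date: str = "2024-12-31",
) -> ResourceSpec:
    """Assemble one resource: formats from the highest-priority matching
    modality rule, content from the content-mapping rules; fully
    deterministic in its inputs."""
    base = rule_base or default_rule_base()
    formats, modality_rule = _select_modality(profile, topic_label, base)
    elements = map_content(topic_label, entities, rules, kgraph,
                           rule_base=base, source_date=source_date)
    provenance = [modality_rule] + [e.rule_id for e in elements]
    return ResourceSpec(formats=formats, content_elements=elements,
                        provenance=provenance)


def render_markdown(spec: ResourceSpec, tier: str = "public") -> str:
    """Render a ResourceSpec as Markdown.  The 'professional' tier exposes
    provenance and full citations; the 'public' tier is the simplified
    one-core-fact presentation of the same spec."""
    lines = [f"# Health education resource ({tier} version)", ""]
    lines.append("Formats: " + ", ".join(spec.formats))
    lines.append("")
    for el in spec.content_elements:
        head = el.kind.replace("_", " ").title()
        lines.append(f"## {head}: {el.knowledge_element}")
        lines.append(el.text)
        if el.kind == "knowledge_card":
            lines.append(f"*{el.source_citation} — last updated {el.timeliness}*")
        if tier == "professional":
            lines.append(f"(rule: {el.rule_id})")
        lines.append("")
    return "\n".join(lines)


def detect_and_update(
    graph: KnowledgeGraph,
    tagged_bulletin: TaggedDoc,
    known_entities: set[str] | None = None,
) -> UpdateEvent | None:
    """Fire the knowledge-update pipeline when a bulletin mentions an entity
    absent from the graph (names and aliases); mutates the graph in place.

    Source retrieval is a pluggable stub that returns the triggering
    bulletin itself as the authoritative source.
    """
    known = set(known_entities or ()) | graph.known_surfaces()
    toks = list(tagged_bulletin.tokens)
    new_mention = None
    for m in sorted(tagged_bulletin.mentions, key=lambda m: m.start):
        surface = " ".join(toks[m.start:m.end])
        if surface not in known:
            new_mention = (surface, m)
            break
    if new_mention is None:
        # nothing new: known entities only re-confirm existing triples,
        # so matching edges gain evidence instead of duplicate nodes
        surfaces = {" ".join(toks[m.start:m.end]) for m in
                    tagged_bulletin.mentions}
        for s in sorted(surfaces & set(graph.g.nodes)):
            for t in sorted(surfaces & set(graph.g.nodes)):
                if s == t:
                    continue
                for rel in sorted(_TRIPLE_RELATION.values()):
                    if graph.g.has_edge(s, t, key=rel):
                        graph.add_edge(s, rel, t, evidence=1,
                                       bulletins=[tagged_bulletin.bulletin_id])
        return None

    surface, mention = new_mention
    stages = [UPDATE_STAGES[0], UPDATE_STAGES[1]]  # recognition, retrieval
    node_type = CATEGORY_TO_NODE_TYPE.get(mention.category, "virus")
    triples: list[tuple[str, str, str]] = []
    for other in tagged_bulletin.mentions:
        o_surface = " ".join(toks[other.start:other.end])
        if o_surface == surface or o_surface not in graph.known_surfaces():
            continue
        rel = _TRIPLE_RELATION.get(graph.node_type(o_surface))
        if rel:
            triples.append((surface, rel, o_surface))
    stages.append(UPDATE_STAGES[2])  # triple generation

    graph.add_node(surface, node_type)
    for s, rel, t in triples:
        graph.add_edge(s, rel, t, evidence=1,
                       bulletins=[tagged_bulletin.bulletin_id])
    stages.append(UPDATE_STAGES[3])  # graph update

    brief = (
        f"Science brief: '{surface}' was newly reported in bulletin "
        f"{tagged_bulletin.bulletin_id}. "
        + (f"It is linked to {len(triples)} known element(s). " if triples else "")
        + "Authoritative guidance will be updated as evidence accrues."
    )
    stages.append(UPDATE_STAGES[4])  # brief release
    return UpdateEvent(new_entity=surface, pipeline_stages=stages,
                       resulting_triples=triples, brief=brief)
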