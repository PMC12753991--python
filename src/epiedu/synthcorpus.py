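"""Seeded synthetic epidemic-bulletin corpora with planted ground truth.

A synthetic bulletin is a token stream drawn from a five-topic mixture model
(disjoint per-topic vocabularies by default), into which entity mentions and
co-occurring "item" marker tokens are planted.  Every bulletin records its
generative truth — the document-topic mixture, the token-level topic
assignments, the entity spans, and the included items — so that each
downstream stage (tagging, graph building, topic modelling, rule mining)
can be scored against a known answer.

The corpus emulates the structure of a stratified national bulletin sample:
three epidemic phases with phase-dependent topic mixtures, administrative
strata (national / provincial / municipal at 15% / 35% / 50%), and bulletin
IDs in ``Date_Province_DataType`` form.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

TOPICS = (
    "preventive_measures",
    "virological_characteristics",
    "case_data",
    "medical_resources",
    "science_communication",
)

#: Overall corpus-level topic mixture (relative proportions of the five themes).
OVERALL_TOPIC_MIX = (0.327, 0.241, 0.185, 0.152, 0.095)

ADMIN_LEVELS = ("national", "provincial", "municipal")
DEFAULT_LEVEL_PROPS = {"national": 0.15, "provincial": 0.35, "municipal": 0.50}

PHASES = ("initial", "sustained", "normalized")
DEFAULT_PHASE_WINDOWS = {
    "initial": (_dt.date(2020, 1, 1), _dt.date(2020, 3, 31)),
    "sustained": (_dt.date(2020, 4, 1), _dt.date(2022, 11, 30)),
    "normalized": (_dt.date(2022, 12, 1), _dt.date(2024, 12, 31)),
}

PROVINCES = (
    "Hubei", "Guangdong", "Jiangsu", "Zhejiang", "Sichuan",
    "Shandong", "Henan", "Hunan", "Fujian", "Shaanxi",
)

#: Entity surfaces planted into bulletins, per category.  Surfaces are token
#: tuples; a few are deliberately multi-token so BIO tagging is exercised.
DEFAULT_ENTITY_SURFACES: dict[str, tuple[tuple[str, ...], ...]] = {
    "virus": (("omicron_variant",), ("delta_variant",), ("novel_coronavirus",)),
    "symptom": (("fever",), ("dry_cough",), ("loss_of", "smell")),
    "drug": (("lianhua_qingwen",), ("paxlovid",)),
    "preventive_measure": (
        ("mask_wearing",), ("frequent_handwashing",), ("ventilation",),
        ("social_distancing",), ("nucleic_acid_testing",),
        ("health_code", "verification"),
    ),
    "institution": (("national_health_commission",), ("provincial_cdc",)),
    "location": (("wuhan",), ("suzhou",), ("guangzhou",)),
    "temporal": (("january_2020",), ("past_week",)),
}

ENTITY_CATEGORIES = tuple(DEFAULT_ENTITY_SURFACES)


def _rescale_with_overrides(overrides: dict[int, float]) -> tuple[float, ...]:
    """Fill non-overridden topic weights proportionally to the overall mix."""
    rest = 1.0 - sum(overrides.values())
    base = [OVERALL_TOPIC_MIX[i] for i in range(5) if i not in overrides]
    scale = rest / sum(base)
    out = []
    j = 0
    for i in range(5):
        if i in overrides:
            out.append(overrides[i])
        else:
            out.append(OVERALL_TOPIC_MIX[i] * scale)
            j += 1
    return tuple(out)


#: Phase-dependent topic mixtures.  The initial phase leans on virology and
#: case data (40.2% / 30.1%); the normalized phase on prevention and science
#: communication (38.5% / 15.3%); the long sustained phase carries the
#: overall mixture.
DEFAULT_TOPIC_MIX_BY_PHASE = {
    "initial": _rescale_with_overrides({1: 0.402, 2: 0.301}),
    "sustained": OVERALL_TOPIC_MIX,
    "normalized": _rescale_with_overrides({0: 0.385, 4: 0.153}),
}


@dataclass(frozen=True)
class PlantedItemset:
    """A co-occurrence plant: the antecedent items appear with rate
    ``joint_prob / confidence``; given the antecedent, the consequent items
    co-occur with rate ``confidence`` — so the full set's support is exactly
    ``joint_prob`` in expectation."""

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    joint_prob: float
    confidence: float

    @property
    def items(self) -> tuple[str, ...]:
        return self.antecedent + self.consequent

    @property
    def antecedent_prob(self) -> float:
        return self.joint_prob / self.confidence

    def validate(self) -> None:
        if not (0.0 < self.confidence <= 1.0):
            raise ValidationError(f"confidence {self.confidence} not in (0, 1]")
        if not (0.0 <= self.joint_prob <= self.confidence):
            raise ValidationError(
                f"joint_prob {self.joint_prob} must lie in [0, confidence]"
            )
        if set(self.antecedent) & set(self.consequent):
            raise ValidationError("antecedent and consequent must be disjoint")


DEFAULT_PLANTED_ITEMSETS = (
    PlantedItemset(("mask_wearing",), ("frequent_handwashing",), 0.78, 0.93),
    PlantedItemset(("nucleic_acid_testing",), ("health_code_verification",), 0.65, 0.89),
    PlantedItemset(
        ("omicron_variant", "booster_vaccination"),
        ("breakthrough_infection",),
        0.51, 0.82,
    ),
)

#: P(crowd_gatherings) and P(mask_wearing | crowd_gatherings): bulletins that
#: mention crowd gatherings overwhelmingly also stress mask wearing.
DEFAULT_CROWD_PROB = 0.30
DEFAULT_MASK_GIVEN_CROWD = 0.923


@dataclass
class CorpusConfig:
    """Generator settings; the defaults are the study conditions."""

    n_bulletins: int = 1026
    level_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PROPS))
    phase_windows: dict[str, tuple[_dt.date, _dt.date]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_WINDOWS))
    topic_mix_by_phase: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TOPIC_MIX_BY_PHASE))
    itemset_plants: tuple[PlantedItemset, ...] = DEFAULT_PLANTED_ITEMSETS
    crowd_prob: float = DEFAULT_CROWD_PROB
    mask_given_crowd: float = DEFAULT_MASK_GIVEN_CROWD
    vocab_per_topic: int = 40
    doc_length: int = 60
    doc_topic_concentration: float = 1.0
    entities_per_bulletin: float = 3.0  # Poisson mean
    plant_entities: bool = True
    plant_itemsets: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_bulletins < 0:
            raise ValidationError("n_bulletins must be non-negative")
        if set(self.level_props) != set(ADMIN_LEVELS):
            raise ValidationError(f"level_props keys must be {ADMIN_LEVELS}")
        if abs(sum(self.level_props.values()) - 1.0) > 1e-9:
            raise ValidationError("level_props must sum to 1")
        if any(p < 0 or p > 1 for p in self.level_props.values()):
            raise ValidationError("level_props must lie in [0, 1]")
        if 0 < self.n_bulletins < len(ADMIN_LEVELS):
            raise ValidationError(
                "n_bulletins must be 0 or at least the number of admin strata")
        for phase, mix in self.topic_mix_by_phase.items():
            if phase not in PHASES:
                raise ValidationError(f"unknown phase {phase!r}")
            if len(mix) != len(TOPICS):
                raise ValidationError("each topic mix must have 5 weights")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValidationError(f"topic mix for {phase!r} must sum to 1")
            if any(w < 0 or w > 1 for w in mix):
                raise ValidationError("topic weights must lie in [0, 1]")
        for plant in self.itemset_plants:
            plant.validate()
        if self.vocab_per_topic < 1 or self.doc_length < 1:
            raise ValidationError("vocab_per_topic and doc_length must be >= 1")


@dataclass
class Bulletin:
    """One dated, stratified announcement with planted ground truth."""

    id: str
    date: _dt.date
    province: str
    admin_level: str
    phase: str
    text: list[str]
    truth: dict

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["date"] = self.date.isoformat()
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Bulletin":
        rec = dict(rec)
        rec["date"] = _dt.date.fromisoformat(rec["date"])
        rec.setdefault("truth", {})
        return cls(**rec)


def topic_vocabulary(topic_index: int, vocab_per_topic: int) -> list[str]:
    """Disjoint per-topic vocabulary: topic ``k`` owns tokens ``t{k}_w*``."""
    return [f"t{topic_index}_w{j}" for j in range(vocab_per_topic)]


def largest_remainder_allocation(n: int, props: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` across strata by largest-remainder rounding."""
    quotas = [n * p for p in props]
    counts = [int(np.floor(q)) for q in quotas]
    shortfall = n - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _phase_of(date: _dt.date, windows: dict[str, tuple[_dt.date, _dt.date]]) -> str:
    for phase, (lo, hi) in windows.items():
        if lo <= date <= hi:
            return phase
    raise ValidationError(f"date {date} outside every phase window")


def _sample_items(cfg: CorpusConfig, rng: np.random.Generator) -> set[str]:
    items: set[str] = set()
    for plant in cfg.itemset_plants:
        u = rng.random()
        if u < plant.joint_prob:
            items.update(plant.items)
        elif u < plant.antecedent_prob:
            items.update(plant.antecedent)
    # crowd gatherings are drawn conditionally on mask wearing so that
    # P(mask | crowd) hits the configured rate while P(crowd) stays fixed
    p_mask = next(
        (p.antecedent_prob for p in cfg.itemset_plants
         if p.antecedent == ("mask_wearing",)), 0.0)
    if p_mask > 0:
        joint = cfg.mask_given_crowd * cfg.crowd_prob
        if "mask_wearing" in items:
            p_crowd = joint / p_mask
        else:
            p_crowd = (cfg.crowd_prob - joint) / (1.0 - p_mask)
        if rng.random() < max(0.0, p_crowd):
            items.add("crowd_gatherings")
    return items


def _insert_span(tokens: list[str], surface: tuple[str, ...],
                 mentions: list[dict], rng: np.random.Generator,
                 category: str) -> None:
    pos = int(rng.integers(0, len(tokens) + 1))
    for m in mentions:  # never split an earlier mention's span
        if m["start"] < pos < m["end"]:
            pos = m["end"]
    for m in mentions:
        if m["start"] >= pos:
            m["start"] += len(surface)
            m["end"] += len(surface)
    tokens[pos:pos] = list(surface)
    mentions.append({
        "start": pos, "end": pos + len(surface),
        "category": category, "surface": list(surface),
    })


def generate_corpus(config: CorpusConfig) -> list[Bulletin]:
    """Generate a seeded corpus; deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_bulletins
    if n == 0:
        return []

    level_counts = largest_remainder_allocation(
        n, [config.level_props[lv] for lv in ADMIN_LEVELS])
    levels: list[str] = []
    for lv, c in zip(ADMIN_LEVELS, level_counts):
        levels.extend([lv] * c)
    rng.shuffle(levels)

    epoch = min(lo for lo, _ in config.phase_windows.values())
    horizon = max(hi for _, hi in config.phase_windows.values())
    total_days = (horizon - epoch).days + 1

    surface_category = {
        tuple(s): cat
        for cat, surfaces in DEFAULT_ENTITY_SURFACES.items()
        for s in surfaces
    }
    item_category = {s[0]: cat for s, cat in surface_category.items()
                     if len(s) == 1}

    bulletins: list[Bulletin] = []
    seen_ids: dict[str, int] = {}
    for i in range(n):
        date = epoch + _dt.timedelta(days=int(rng.integers(0, total_days)))
        phase = _phase_of(date, config.phase_windows)
        province = PROVINCES[int(rng.integers(0, len(PROVINCES)))]
        mix = np.asarray(config.topic_mix_by_phase[phase], dtype=float)
        alpha = config.doc_topic_concentration * np.clip(mix, 1e-6, None)
        theta = rng.dirichlet(alpha)
        z = rng.choice(len(TOPICS), size=config.doc_length, p=theta)
        word_ids = rng.integers(0, config.vocab_per_topic, size=config.doc_length)
        tokens = [f"t{k}_w{w}" for k, w in zip(z, word_ids)]
        z_counts = np.bincount(z, minlength=len(TOPICS)).tolist()

        mentions: list[dict] = []
        items: set[str] = set()
        if config.plant_itemsets:
            items = _sample_items(config, rng)
            for item in sorted(items):
                cat = item_category.get(item, "preventive_measure")
                _insert_span(tokens, (item,), mentions, rng, cat)
        if config.plant_entities:
            n_ent = int(rng.poisson(config.entities_per_bulletin))
            surfaces = sorted(surface_category)
            for _ in range(n_ent):
                surf = surfaces[int(rng.integers(0, len(surfaces)))]
                _insert_span(tokens, surf, mentions, rng,
                             surface_category[surf])

        base_id = f"{date.isoformat()}_{province}_Bulletin"
        k = seen_ids.get(base_id, 0)
        seen_ids[base_id] = k + 1
        bid = base_id if k == 0 else f"{base_id}{k + 1}"

        bulletins.append(Bulletin(
            id=bid, date=date, province=province,
            admin_level=levels[i], phase=phase, text=tokens,
            truth={
                "theta": theta.tolist(),
                "z_counts": z_counts,
                "entities": mentions,
                "items": sorted(items),
            },
        ))
    return bulletins


@dataclass
class TruthSummary:
    """Empirical statistics of planted truth (computed from annotations,
    never from text analysis)."""

    topic_shares: dict[str, float]
    itemset_joint_freq: dict[tuple[str, ...], float]
    itemset_conditional: dict[tuple[tuple[str, ...], tuple[str, ...]], float]
    entity_counts: dict[str, int]


def planted_truth_summary(
    corpus: Sequence[Bulletin],
    itemsets: Iterable[PlantedItemset] = DEFAULT_PLANTED_ITEMSETS,
) -> TruthSummary:
    if not corpus:
        raise ValidationError("corpus is empty")
    z_totals = np.zeros(len(TOPICS))
    entity_counts: dict[str, int] = {}
    for b in corpus:
        z_totals += np.asarray(b.truth["z_counts"], dtype=float)
        for m in b.truth.get("entities", []):
            entity_counts[m["category"]] = entity_counts.get(m["category"], 0) + 1
    shares = z_totals / z_totals.sum()

    joint: dict[tuple[str, ...], float] = {}
    cond: dict[tuple[tuple[str, ...], tuple[str, ...]], float] = {}
    n = len(corpus)
    for plant in itemsets:
        full = set(plant.items)
        ante = set(plant.antecedent)
        n_full = sum(1 for b in corpus if full <= set(b.truth.get("items", [])))
        n_ante = sum(1 for b in corpus if ante <= set(b.truth.get("items", [])))
        joint[plant.items] = n_full / n
        cond[(plant.antecedent, plant.consequent)] = (
            n_full / n_ante if n_ante else 0.0)
    return TruthSummary(
        topic_shares={t: float(s) for t, s in zip(TOPICS, shares)},
        itemset_joint_freq=joint,
        itemset_conditional=cond,
        entity_counts=entity_counts,
    )


def simulate_transactions(
    plants: Iterable[PlantedItemset],
    n_transactions: int,
    seed: int,
    filler_items: Sequence[str] = ("temperature_check", "travel_report"),
    filler_prob: float = 0.2,
) -> list[set[str]]:
    """Item transactions with the configured co-occurrence structure, without
    the surrounding token stream (used for rule-mining calibration runs)."""
    if n_transactions < 1:
        raise ValidationError("need at least one transaction")
    rng = np.random.default_rng(seed)
    out: list[set[str]] = []
    for _ in range(n_transactions):
        items: set[str] = set()
        for plant in plants:
            u = rng.random()
            if u < plant.joint_prob:
                items.update(plant.items)
            elif u < plant.antecedent_prob:
                items.update(plant.antecedent)
        for f in filler_items:
            if rng.random() < filler_prob:
                items.add(f)
        out.append(items)
    return out


def write_jsonl(corpus: Iterable[Bulletin], path, drop_truth: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in corpus:
            rec = b.to_record()
            if drop_truth:
                rec.pop("truth", None)
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_jsonl(path) -> list[Bulletin]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Bulletin.from_record(json.loads(line)))
    return out
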