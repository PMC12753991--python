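"""Closed-loop orchestration: simulate/ingest -> preprocess -> graph ->
topics -> rule mining -> resource generation -> evaluation, behind one
seeded configuration with a structured run manifest.

Each stage writes its artifacts into the run directory and records file
checksums, parameters and timings in the manifest, so two runs with the
same configuration can be compared checksum-by-checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import assocmine, kgraph, resourcegen, synthcorpus, tameval, textprep, topicmodel
from .errors import DependencyError, ValidationError

STAGES = (
    "simulate_corpus", "preprocess", "build_graph", "topics",
    "mine_rules", "generate", "evaluate",
)

_UPSTREAM = {
    "simulate_corpus": (),
    "preprocess": ("simulate_corpus",),
    "build_graph": ("preprocess",),
    "topics": ("preprocess",),
    "mine_rules": ("preprocess",),
    "generate": ("build_graph", "topics", "mine_rules"),
    "evaluate": ("generate",),
}

DEFAULT_PATTERNS = (
    kgraph.RelationPattern("virus", frozenset({"via", "经"}),
                           "transmission_mode", "transmission_pathway", 3),
    kgraph.RelationPattern("virus", frozenset(), "preventive_measure",
                           "preventive_measure", 4),
    kgraph.RelationPattern("virus", frozenset(), "drug",
                           "therapeutic_drug", 4),
    kgraph.RelationPattern("location", frozenset(), "virus",
                           "geographical_location", 4),
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, independent of execution order."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_bulletins: int = 200
    n_respondents: int = 305
    lda_k: int = 5
    lda_iterations: int = 300
    min_support: float = 0.3
    min_confidence: float = 0.7
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)


@dataclass
class RunManifest:
    seed: int
    parameters: dict
    stages: dict[str, dict]  # stage -> {outputs: {path: sha256}, seconds}

    def all_files(self) -> dict[str, str]:
        out = {}
        for info in self.stages.values():
            out.update(info["outputs"])
        return out

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        parameters={
            "n_bulletins": config.n_bulletins,
            "n_respondents": config.n_respondents,
            "lda_k": config.lda_k,
            "lda_iterations": config.lda_iterations,
            "min_support": config.min_support,
            "min_confidence": config.min_confidence,
        },
        stages={},
    )

    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        for up in _UPSTREAM[stage]:
            if up not in manifest.stages:
                raise DependencyError(stage, up)
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FNS[stage](config, out, state)
        except (DependencyError, ValidationError):
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest.stages[stage] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
        }
    manifest.write(out / "manifest.json")
    return manifest


# -- stage implementations -------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cfg = synthcorpus.CorpusConfig(
        n_bulletins=config.n_bulletins,
        seed=stage_seed(config.seed, "simulate_corpus"))
    corpus = synthcorpus.generate_corpus(cfg)
    path = out / "corpus.jsonl"
    synthcorpus.write_jsonl(corpus, path)
    state["corpus"] = corpus
    return [path]


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> list[Path]:
    corpus, dropped = textprep.deduplicate(state["corpus"])
    lexicon = textprep.lexicon_from_corpus_truth(corpus, min_freq=1)
    docs = [b.text for b in corpus]
    filtered, report = textprep.filter_tokens(docs, lexicon)
    tagged = [
        kgraph.TaggedDoc(b.id, b.text,
                         textprep.tag_entities(b.text, lexicon, b.id))
        for b in corpus
    ]
    state.update(corpus=corpus, lexicon=lexicon, docs=filtered, tagged=tagged)
    path = out / "tagged.jsonl"
    with open(path, "w", encoding="utf-8") as fh:
        for td in tagged:
            fh.write(json.dumps({
                "id": td.bulletin_id,
                "tokens": list(td.tokens),
                "mentions": [
                    {"start": m.start, "end": m.end, "category": m.category}
                    for m in td.mentions],
            }, sort_keys=True) + "\n")
    rpath = out / "filter_report.json"
    rpath.write_text(json.dumps(dataclasses.asdict(report), sort_keys=True))
    return [path, rpath]


def _stage_graph(config: RunConfig, out: Path, state: dict) -> list[Path]:
    graph = kgraph.extract_relations(state["tagged"], DEFAULT_PATTERNS)
    graph = kgraph.fuse(graph)
    state["graph"] = graph
    path = out / "graph.json"
    graph.write_json(path)
    gpath = out / "graph.graphml"
    graph.write_graphml(gpath)
    return [path, gpath]


def _stage_topics(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cfg = topicmodel.LDAConfig(
        k=config.lda_k, iterations=config.lda_iterations,
        seed=stage_seed(config.seed, "topics"))
    lda_state, report = topicmodel.fit_lda(state["docs"], cfg)
    truth_vocabs = [
        synthcorpus.topic_vocabulary(i, 40) for i in range(len(synthcorpus.TOPICS))]
    matching = topicmodel.match_topics_to_truth(
        report.phi, lda_state.vocab, truth_vocabs)
    doms = topicmodel.dominant_topics(report.theta)
    chi2 = topicmodel.phase_topic_chi2(
        [b.phase for b in state["corpus"]], doms.tolist())
    state.update(lda_state=lda_state, lda_report=report, matching=matching)
    path = out / "topics.json"
    path.write_text(json.dumps({
        "k": cfg.k,
        "perplexity": report.perplexity,
        "corpus_shares": report.corpus_shares.tolist(),
        "topic_matching": {synthcorpus.TOPICS[t]: int(f)
                           for t, f in matching.items()},
        "phase_topic_chi2": {"statistic": chi2.statistic, "df": chi2.df,
                             "p_value": chi2.p_value},
    }, sort_keys=True, indent=1))
    return [path]


def _stage_mine(config: RunConfig, out: Path, state: dict) -> list[Path]:
    tx = assocmine.transactions_from_bulletins(state["corpus"])
    tx = [t for t in tx if t]
    cfg = assocmine.AssocConfig(min_support=config.min_support,
                                min_confidence=config.min_confidence)
    frequent = assocmine.apriori(tx, cfg)
    rules = assocmine.induce_rules(frequent, tx, cfg)
    state["rules"] = rules
    path = out / "rules.json"
    path.write_text(json.dumps([
        {"antecedent": sorted(r.antecedent), "consequent": sorted(r.consequent),
         "support": float(r.support), "confidence": float(r.confidence)}
        for r in rules], sort_keys=True, indent=1))
    return [path]


def _stage_generate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    entities = sorted(state["graph"].g.nodes)
    profiles = [
        resourcegen.UserProfile(age_years=70, education="high_school"),
        resourcegen.UserProfile(age_years=25, education="below_high_school"),
        resourcegen.UserProfile(age_years=35, education="college",
                                ehl_group="high"),
    ]
    source_date = max(b.date for b in state["corpus"]).isoformat()
    specs = []
    paths = []
    for i, profile in enumerate(profiles):
        spec = resourcegen.generate_resource(
            "preventive_measures", entities, state["rules"], profile,
            state["graph"], source_date=source_date)
        specs.append(spec)
        mpath = out / f"resource_{i}.md"
        mpath.write_text(resourcegen.render_markdown(spec))
        paths.append(mpath)
    jpath = out / "resources.json"
    jpath.write_text(json.dumps([
        {"formats": s.formats, "provenance": s.provenance,
         "elements": [dataclasses.asdict(e) for e in s.content_elements]}
        for s in specs], sort_keys=True, indent=1))
    state["resources"] = specs
    return paths + [jpath]


def _stage_evaluate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cfg = tameval.SurveyConfig(
        n_respondents=config.n_respondents,
        seed=stage_seed(config.seed, "evaluate"))
    responses = tameval.simulate_survey(cfg)
    spath = out / "survey.csv"
    tameval.to_dataframe(responses).to_csv(spath, index=False)
    rel = tameval.reliability_report(responses)
    paths_res = tameval.fit_paths(responses)
    mod = tameval.moderation_hierarchy(responses)
    logit = tameval.logit_effectiveness(responses)
    chi2 = tameval.format_preference_chi2(responses)
    epath = out / "evaluation.json"
    epath.write_text(json.dumps({
        "cronbach_alpha": rel.cronbach_alpha,
        "ave": rel.ave,
        "path_betas": paths_res.betas,
        "path_t_values": paths_res.t_values,
        "moderation_delta_r2": mod.delta_r2,
        "odds_ratios": logit.odds_ratio,
        "format_chi2": {"statistic": chi2.statistic, "df": chi2.df,
                        "p_value": chi2.p_value},
    }, sort_keys=True, indent=1))
    return [spath, epath]


_STAGE_FNS = {
    "simulate_corpus": _stage_simulate,
    "preprocess": _stage_preprocess,
    "build_graph": _stage_graph,
    "topics": _stage_topics,
    "mine_rules": _stage_mine,
    "generate": _stage_generate,
    "evaluate": _stage_evaluate,
}
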