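# epiedu

Toolkit for turning official epidemic bulletins into personalized
health-education resources, with a full statistical evaluation arm — an
"analyze → generate → evaluate" closed loop for crisis communication
research.

During a public-health emergency, government bulletins are the
authoritative information source, but they arrive as a torrent of text.
`epiedu` mines that text into structured knowledge and reassembles it into
audience-adapted educational material:

1. **Analyze** — clean and segment bulletin text, tag entities in seven
   categories (virus, symptom, drug, preventive measure, institution,
   location, temporal) with a BIO dictionary tagger, build a typed
   knowledge graph from trigger-pattern relation extraction with synonym
   fusion, fit an LDA topic model by collapsed Gibbs sampling
   (α = 0.1, β = 0.01, K selected by held-out perplexity), and mine
   association rules with Apriori (min support 0.3, min confidence 0.7).
2. **Generate** — a declarative YAML rule base maps mined knowledge to
   content elements (framework sections, knowledge cards with mandatory
   source citations, risk alerts, comparative charts, link-outs) and maps
   user profiles to modality bundles (60+ → audio narration + large-font
   text; below-high-school education → short video + infographic;
   otherwise interactive Q&A + long-form text, with topic-specific
   overrides).  An update trigger detects unseen entities and runs the
   recognition → retrieval → triple generation → graph update → brief
   release pipeline.
3. **Evaluate** — a Technology Acceptance Model (TAM) battery: Cronbach's
   α and AVE reliability, composite path analysis
   (PEOU → PU → BI with eHealth-literacy moderation), hierarchical
   moderation regression, age × format preference chi-square, and a binary
   logistic regression of perceived effectiveness fitted by IRLS.

Because no public bulletin corpus or survey data set exists, the package
ships first-class **synthetic generators** with planted ground truth: a
stratified bulletin simulator (three epidemic phases, 15/35/50
national/provincial/municipal strata, five latent topics, planted entity
spans and co-occurring item sets) and a survey simulator with a planted
structural model.  Every analysis stage can therefore be validated by
parameter recovery.

## Worked example

```python
from epiedu import synthcorpus as sc, assocmine as am, tameval as tv, topicmodel as tm

corpus = sc.generate_corpus(sc.CorpusConfig(n_bulletins=300, seed=11))

tx = [t for t in am.transactions_from_bulletins(corpus) if t]
cfg = am.AssocConfig(min_support=0.3, min_confidence=0.7)
rules = am.induce_rules(am.apriori(tx, cfg), tx, cfg)

resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=305, seed=11))
paths = tv.fit_paths(resp)
```

prints, for the planted mask-wearing → frequent-handwashing pattern and
the planted PU → BI path:

```
bulletins: 300 | example id: 2024-01-13_Sichuan_Bulletin
mask_wearing -> frequent_handwashing: support=0.790 confidence=0.951
PU->BI beta = 0.42 (t=8.64)
```

The generator plants the two-item pattern with joint probability 0.78 and
conditional rate 0.93; the miner recovers 0.790/0.951 from 300 bulletins
(binomial noise at this sample size).  The survey simulator plants a
standardized PU → BI coefficient of 0.42, and the composite path fit
recovers it.  Fitting a K = 5 topic model on a 1,026-bulletin corpus with
the default topic weights recovers a preventive-measures share of ~31%
against a planted 32.7%, and a logistic fit on 5,000 simulated respondents
recovers the planted official-source odds ratio of 2.05 as 2.06.

A command-line interface exposes each stage
(`epiedu simulate-corpus | preprocess | build-graph | topics | mine-rules |
generate | simulate-survey | evaluate | run-all`); `run-all` executes the
whole loop into one directory with a checksummed run manifest.

## Documentation

See `docs/methods.md` for the models, estimation choices, generator
assumptions, and known limitations.
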