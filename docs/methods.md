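# Methods

This note records the models implemented in `epiedu`, the estimation and
numerical choices made where the design was genuinely open, what the
synthetic generators do and do not emulate, and the package's known
limitations.

## Synthetic bulletin corpus (`synthcorpus`)

A bulletin is a token stream, not prose.  Each document draws a date
uniformly over 2020-01-01 … 2024-12-31, which fixes its epidemic phase
(initial: 2020-01–2020-03; sustained: 2020-04–2022-11; normalized:
2022-12–2024-12); administrative strata are allocated exactly by
largest-remainder rounding of the 15% / 35% / 50%
national/provincial/municipal proportions.  Topic structure follows a
five-topic mixture model: the document's topic distribution is
θ_d ~ Dirichlet(c · m_phase) with concentration c = 1 (bulletins are
theme-dominant, as single-purpose government announcements are), and each
of the 60 tokens draws a topic from θ_d and a word uniformly from that
topic's 40-word vocabulary.  Per-topic vocabularies are disjoint by
default so that topic recovery is well-posed; overlap can be introduced by
supplying custom mixes.  The overall topic weights are
(preventive measures 32.7%, virological characteristics 24.1%, case data
18.5%, medical resources 15.2%, science communication 9.5%); the initial
phase overrides virology/case-data to 40.2%/30.1% and the normalized phase
overrides prevention/science-communication to 38.5%/15.3%, with the
remaining mass spread proportionally to the overall weights.

Item sets are planted hierarchically: for a pattern with joint probability
p and confidence c, the antecedent appears with probability p/c and, given
the antecedent, the consequent co-occurs with probability c — so the full
set's support is exactly p in expectation and the antecedent→consequent
confidence is exactly c.  Defaults: {mask-wearing, frequent handwashing}
at 0.78/0.93, {nucleic-acid testing, health-code verification} at
0.65/0.89, and the ternary {Omicron variant, booster vaccination,
breakthrough infection} at 0.51/0.82.  Crowd-gathering mentions are drawn
conditionally on mask-wearing so that P(mask | crowd) = 0.923 while
P(crowd) = 0.30.  Entity mentions (some multi-token) are inserted at
random positions without ever splitting an earlier span, and every
generative fact — θ_d, token-level topic counts, entity spans, included
items — is stored under the bulletin's `truth` key so downstream stages
can be scored, or run blind by dropping it.

What the generator does **not** emulate: fluent Chinese syntax, realistic
word frequency (Zipf) profiles, topic-correlated entity placement, or
bulletin length variation.  Passing recovery tests therefore demonstrates
the correctness of the estimators under the stated generative model, not
performance on real bulletin prose.

## Preprocessing (`textprep`)

Cleaning strips markup tags, table delimiters, and characters outside the
allowed classes (CJK + word characters by default) and is idempotent.
Segmentation is greedy leftmost-longest dictionary matching with
single-character fallback; lexicon entries are never split and token
concatenation reproduces the input exactly.  Low-frequency filtering
(threshold 5 by default) counts frequencies on the raw segmented corpus
before any removal, so stopword and frequency filtering commute.
The BIO tagger emits maximal leftmost-longest lexicon matches; evaluation
is exact-span, exact-category micro-averaged P/R/F1.  With the lexicon
equal to the planted vocabulary and no noise, tagger F1 is exactly 1 —
this is the designed oracle condition, not a claim about dictionary
tagging of real text.

## Knowledge graph (`kgraph`)

Nodes are typed by entity category (plus `drug` and `transmission_mode`,
needed to represent therapeutic-drug and transmission-pathway examples);
edges are one of five directed relation types and carry an evidence count
and the set of supporting bulletin IDs.  Relation extraction matches
(source mention, trigger token, target mention) within a token window.
Fusion resolves synonym chains to canonical names (cycles are rejected),
unions aliases, re-points edges, and sums parallel evidence — total
evidence mass is conserved; surfaces observed with conflicting types are
resolved by (surface, context-token) rules or flagged unresolved.
Retrieval is a triple-pattern API (type?, relation?, type?) with sorted,
deterministic results.  Conventions chosen where the field offers several:
subgraph density is directed, E/(V(V−1)), counting parallel edges once;
chain frequency is the number of bulletins whose provenance supports every
edge of the chain jointly; association strength is the overlap coefficient
P(a,b)/max(P(a),P(b)) — bounded, symmetric, and simple, but an explicit
modelling choice rather than a canonical definition.

## Topic model (`topicmodel`)

Collapsed Gibbs sampling with symmetric priors (α = 0.1 document-topic,
β = 0.01 topic-word, 1,000 sweeps by default).  The full conditional is
P(z_i = k) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ); estimates use the final
count state, θ̂_dk = (n_dk + α)/(N_d + Kα) and
φ̂_kw = (n_kw + β)/(n_k + Vβ).  One uniform per token per sweep is drawn
outside the kernel from a seeded PCG64 generator; the numba-jitted kernel
and the pure-Python fallback consume the identical stream with identical
arithmetic, so chains are bit-identical either way and fully deterministic
per seed.

Reported perplexity is exp(−mean per-token log-likelihood) on the training
corpus.  Topic-count selection cannot use training perplexity (it
decreases monotonically in K), so `select_k` uses document completion:
each document's tokens are split 50/50 by seed, candidates are fitted on
one half and scored on the held-out half (held-out tokens unseen in the
fit half are skipped); ties break to the smaller K.  Fitted topics are
matched to planted topics by maximum-weight bipartite matching
(Hungarian assignment) on φ mass over the planted vocabularies, so label
permutations never look like failures.  A document's dominant topic is the
argmax of θ̂ (ties to the lowest index), feeding the phase × topic Pearson
chi-square.

## Association mining (`assocmine`)

Level-wise Apriori with the subset-pruning step; supports and confidences
are exact `Fraction`s over transaction counts, and float thresholds such
as 0.3 are interpreted as the exact rationals they print as, so boundary
cases (support exactly at the floor) are decided without tolerance.  Rule
induction enumerates all non-trivial antecedent/consequent splits; a
ternary set's maximum-confidence split is surfaced as its summary.  A
brute-force subset enumerator serves as the independent oracle for small
instances and is asserted equal on randomized cases.

## Resource generation (`resourcegen`)

The rule base is data (YAML), not code.  Modality rules carry priorities:
topic × demographic rules (priority 100) outrank demographic defaults
(50/40/0), which is how "virological characteristics + age ≥ 60 → video +
audio narration" coexists with the general "60+ → audio narration +
large-font text".  Content rules fire independently on entities, rule
items, or item presence/absence patterns, and every emitted element
records the knowledge element and rule ID that produced it (provenance
completeness).  Knowledge cards always carry a source citation and a
timeliness date — credibility is a structural requirement, not an option.
The professional/public tiers are two renderings of the same resource
specification.  The update trigger treats source retrieval as a pluggable
stub returning the triggering bulletin; re-mentions of an already-known
entity increment the evidence of its existing triples instead of creating
duplicate nodes.

## Survey simulation and evaluation (`tameval`)

The simulator plants: PEOU ~ N(0,1); PU = 0.38·PEOU + noise;
BI = 0.42·PU + 0.31·PEOU + 0.18·(eHL_c·PU) + 0.22·(eHL_c·PEOU) + noise,
with eHL a balanced binary moderator centered to ±0.5 and the residual
scaled analytically so BI has exactly unit variance.  Likert items load on
their construct (default loading 0.8) and are discretized at equiprobable
standard-normal quintile cut-points; the continuous-limit configuration
(loading 1, no discretization) removes measurement attenuation and is the
configuration used for exact path-recovery checks.  eHEALS items are
generated with a ±1 SD group separation, so the median split (strictly
greater than the median → high; ties low) recovers the planted moderator
with negligible misclassification.  The binary effectiveness outcome is
Bernoulli with log-odds Σ ln(OR_j)·x_j over the indicators age 60+
(OR 0.76), college education (1.52), high eHL (1.87), and official-source
trust (2.05), intercept 0 by default.  Demographics: age bands 25/55/20,
higher education 62.6%, official-source trust 70%; format preferences are
age-band dependent (older respondents lean strongly to video/audio).

Estimation: path analysis uses construct composites (item means,
z-scored) with OLS — PU on PEOU, then BI on PU, PEOU and the two
mean-centered interactions — reporting standardized betas and OLS
t-values.  This is a composite-level stand-in for PLS-SEM: with
equal-loading reflective constructs the two coincide at the path level,
and unlike PLS-SEM every detail (weighting, centering, inference) is
fully specified here.  Hierarchical moderation regression reports ΔR²
between the main-effects and interaction models (non-negative by
nesting).  The logistic regression is fitted by hand-rolled IRLS
(tolerance 1e-8 on the coefficient step, max 100 iterations) with a
complete-separation pre-check that names the separating variable;
standard errors come from the inverse Fisher information, and the fit is
cross-checked against an independent maximum-likelihood implementation in
the test suite.  Cronbach's α uses sample (n−1) variances; AVE is the
mean squared standardized loading, with item-composite correlations used
as loadings when reporting per-construct reliability.

## Pipeline (`pipeline`)

Stages run in a fixed dependency order (simulate → preprocess → graph /
topics / rules → generate → evaluate); disabling a stage whose consumer is
enabled raises a dependency error naming the stage.  Per-stage seeds
derive from the master seed by SHA-256 of `"{seed}:{stage}"` (kept below
2³¹), so stage-level reproducibility is independent of execution order.
The manifest lists every produced file with its SHA-256, the stage
parameters, and timings; identical configurations yield identical
checksums.

## Problem sizes

Recovery studies use the study-scale conditions: 1,026 bulletins of 60
tokens for topic-share recovery (K = 5, 1,000 sweeps); 2,000 transactions
× 20 seeds for rule recovery; 50 replicates of n = 305 surveys for path
recovery; 20 replicates of n = 5,000 for odds-ratio recovery.  Unit and
property tests use smaller corpora (tens of documents, ≤ a few hundred
sweeps), chosen as the smallest sizes at which the checked statistics are
stable at their stated tolerances.

## Known limitations

* The dictionary tagger and pattern extractor are deliberately simple
  stand-ins for learned sequence and relation models; their perfect
  scores on planted corpora say nothing about real-text F1.
* Real Chinese prose segmentation is out of scope; the segmenter contract
  (round-trip, entries never split) is what downstream stages rely on.
* Topic-share recovery assumes separable vocabularies; heavily mixed
  documents (Dirichlet concentration well above 1) can defeat a
  sparse-prior sampler's labeling even when the corpus-level mixture is
  correct.
* Training-corpus perplexity is reported as fitted-model diagnostics;
  only `select_k` uses held-out evaluation.
* The effectiveness logistic model conditions on the derived eHL group;
  the median split's (tiny) misclassification attenuates the eHL odds
  ratio by a correspondingly tiny amount.
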