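"""LDA topic modelling by collapsed Gibbs sampling, perplexity-based topic
count selection, topic-share reporting, and the phase-by-topic chi-square
test.

The sampler uses symmetric Dirichlet priors α (document-topic) and β
(topic-word) and estimates, from the final count state,

    θ̂_dk = (n_dk + α) / (N_d + Kα),    φ̂_kw = (n_kw + β) / (n_k + Vβ).

Perplexity is exp(−mean per-token log-likelihood) under the mixture
Σ_k θ̂_dk φ̂_kw, computed on the training corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2_contingency

from ._gibbs import run_sweeps
from .errors import ValidationError


@dataclass
class LDAConfig:
    k: int = 5
    alpha: float = 0.1
    beta: float = 0.01
    iterations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("alpha and beta must be positive")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


@dataclass
class LDAState:
    z: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    vocab: dict[str, int]
    doc_lengths: np.ndarray
    config: LDAConfig

    def check_counts(self) -> None:
        """Count bookkeeping invariants (cheap; asserted in tests)."""
        if (self.n_dk < 0).any() or (self.n_kw < 0).any() or (self.n_k < 0).any():
            raise AssertionError("negative Gibbs counts")
        if not np.array_equal(self.n_dk.sum(axis=1), self.doc_lengths):
            raise AssertionError("doc-topic counts do not sum to doc lengths")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise AssertionError("topic-word counts do not sum to topic totals")

    def theta(self) -> np.ndarray:
        a = self.config.alpha
        k = self.config.k
        return (self.n_dk + a) / (self.doc_lengths[:, None] + k * a)

    def phi(self) -> np.ndarray:
        b = self.config.beta
        v = len(self.vocab)
        return (self.n_kw + b) / (self.n_k[:, None] + v * b)


@dataclass
class TopicReport:
    theta: np.ndarray
    phi: np.ndarray
    corpus_shares: np.ndarray
    perplexity: float
    topic_labels: dict[int, str] = field(default_factory=dict)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def _encode(docs: Sequence[Sequence[str]],
            vocab: dict[str, int] | None = None):
    if vocab is None:
        vocab = {}
        for doc in docs:
            for t in doc:
                if t not in vocab:
                    vocab[t] = len(vocab)
        strict = False
    else:
        strict = True
    encoded = []
    for doc in docs:
        ids = []
        for t in doc:
            if t not in vocab:
                if strict:
                    raise ValidationError(f"out-of-vocabulary token {t!r}")
                vocab[t] = len(vocab)
            ids.append(vocab[t])
        encoded.append(np.asarray(ids, dtype=np.int64))
    return encoded, vocab


def fit_lda(docs: Sequence[Sequence[str]],
            config: LDAConfig) -> tuple[LDAState, TopicReport]:
    """Fit by collapsed Gibbs sampling; deterministic for a fixed seed."""
    config.validate()
    docs = [d for d in docs]
    if not docs or all(len(d) == 0 for d in docs):
        raise ValidationError("corpus is empty")
    encoded, vocab = _encode(docs)
    doc_lengths = np.array([len(d) for d in encoded], dtype=np.int64)
    tokens = np.concatenate([d for d in encoded if len(d)]) if encoded else \
        np.empty(0, dtype=np.int64)
    doc_of = np.repeat(np.arange(len(encoded), dtype=np.int64), doc_lengths)

    k = config.k
    v = len(vocab)
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, k, size=tokens.shape[0]).astype(np.int64)
    n_dk = np.zeros((len(encoded), k), dtype=np.int64)
    n_kw = np.zeros((k, v), dtype=np.int64)
    n_k = np.zeros(k, dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, tokens), 1)
    np.add.at(n_k, z, 1)

    run_sweeps(tokens, doc_of, z, n_dk, n_kw, n_k,
               float(config.alpha), float(config.beta),
               config.iterations, rng)

    state = LDAState(z=z, n_dk=n_dk, n_kw=n_kw, n_k=n_k, vocab=vocab,
                     doc_lengths=doc_lengths, config=config)
    state.check_counts()
    theta = state.theta()
    phi = state.phi()
    shares = n_k / n_k.sum()
    report = TopicReport(theta=theta, phi=phi,
                         corpus_shares=shares,
                         perplexity=perplexity(state, docs))
    return state, report


def perplexity(state: LDAState, docs: Sequence[Sequence[str]],
               on_oov: str = "error") -> float:
    """exp(−Σ_d Σ_w log Σ_k θ̂_dk φ̂_kw / Σ_d N_d) on pre-mapped docs.

    ``on_oov='skip'`` drops out-of-vocabulary tokens instead of raising
    (used for held-out evaluation, where a token may not occur in the
    fitted half of the corpus).
    """
    if on_oov == "skip":
        docs = [[t for t in d if t in state.vocab] for d in docs]
    encoded, _ = _encode(docs, vocab=state.vocab)
    theta = state.theta()
    phi = state.phi()
    loglik = 0.0
    n_tokens = 0
    for d, ids in enumerate(encoded):
        if len(ids) == 0:
            continue
        p = theta[d] @ phi[:, ids]
        loglik += float(np.log(p).sum())
        n_tokens += len(ids)
    if n_tokens == 0:
        raise ValidationError("no tokens to evaluate")
    return float(np.exp(-loglik / n_tokens))


def select_k(docs: Sequence[Sequence[str]], candidate_ks: Sequence[int],
             config: LDAConfig,
             holdout_fraction: float = 0.5) -> tuple[int, dict[int, float]]:
    """argmin held-out perplexity over candidate topic counts (ties ->
    smaller k).

    Uses document completion: each document's tokens are split (seeded)
    into a fit half and a held-out half; candidates are fitted on the fit
    halves and scored on the held-out halves with the fitted θ̂ and φ̂.
    Training perplexity would decrease monotonically in k and could never
    select against over-parameterization.  All candidate fits share the
    base config and seed derivation.
    """
    if not candidate_ks:
        raise ValidationError("candidate_ks is empty")
    if not (0 < holdout_fraction < 1):
        raise ValidationError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    fit_half: list[list[str]] = []
    held_half: list[list[str]] = []
    for doc in docs:
        doc = list(doc)
        idx = rng.permutation(len(doc))
        n_hold = int(round(holdout_fraction * len(doc)))
        if len(doc) > 1:
            n_hold = min(max(n_hold, 1), len(doc) - 1)
        else:
            n_hold = 0
        hold = set(idx[:n_hold].tolist())
        fit_half.append([t for i, t in enumerate(doc) if i not in hold])
        held_half.append([t for i, t in enumerate(doc) if i in hold])

    perps: dict[int, float] = {}
    for k in candidate_ks:
        cfg = LDAConfig(k=k, alpha=config.alpha, beta=config.beta,
                        iterations=config.iterations, seed=config.seed)
        state, _ = fit_lda(fit_half, cfg)
        perps[k] = perplexity(state, held_half, on_oov="skip")
    best = min(sorted(perps), key=lambda k: (perps[k], k))
    return best, perps


def dominant_topics(theta: np.ndarray) -> np.ndarray:
    """Per-document argmax of θ̂ (ties -> lowest topic index)."""
    return np.argmax(theta, axis=1)


def phase_topic_chi2(phases: Sequence[str],
                     topics: Sequence[int]) -> Chi2Result:
    """Pearson chi-square on the phase × dominant-topic contingency table."""
    if len(phases) != len(topics):
        raise ValidationError("phases and topics must align")
    phase_labels = sorted(set(phases))
    topic_labels = sorted(set(topics))
    table = np.zeros((len(phase_labels), len(topic_labels)))
    pi = {p: i for i, p in enumerate(phase_labels)}
    ti = {t: i for i, t in enumerate(topic_labels)}
    for p, t in zip(phases, topics):
        table[pi[p], ti[t]] += 1
    return pearson_chi2(table)


def pearson_chi2(table: np.ndarray) -> Chi2Result:
    """χ² = Σ (O−E)²/E with E from row/column margins (no continuity
    correction); errors out on zero expected cells with pooling guidance."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("need a table with at least 2 rows and columns")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        raise ValidationError(
            "expected count of 0 in a cell; pool sparse rows/columns first")
    stat, p, df, exp = chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(stat), df=int(df),
                      p_value=float(p), expected=exp)


def match_topics_to_truth(
    phi: np.ndarray, vocab: dict[str, int],
    truth_vocabularies: Sequence[Sequence[str]],
) -> dict[int, int]:
    """Map truth topic index -> fitted topic index by maximum-weight
    bipartite matching on φ mass over each truth vocabulary, so label
    permutation never causes spurious mismatches."""
    n_truth = len(truth_vocabularies)
    k = phi.shape[0]
    weight = np.zeros((n_truth, k))
    for t, words in enumerate(truth_vocabularies):
        ids = [vocab[w] for w in words if w in vocab]
        if ids:
            weight[t] = phi[:, ids].sum(axis=1)
    rows, cols = linear_sum_assignment(-weight)
    return {int(r): int(c) for r, c in zip(rows, cols)}
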