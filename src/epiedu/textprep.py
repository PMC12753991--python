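"""Bulletin preprocessing: cleaning, dictionary segmentation, deduplication,
stop/low-frequency filtering, and BIO entity tagging over seven categories.

Segmentation is greedy leftmost-longest dictionary matching with a
single-character fallback — a deliberately lightweight stand-in with the
same downstream contract as a full segmenter: lexicon entries are never
split and the concatenation of tokens reproduces the input.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .synthcorpus import Bulletin

#: The seven entity categories tagged in bulletins.
CATEGORIES = (
    "virus", "symptom", "drug", "preventive_measure",
    "institution", "location", "temporal",
)

_TAG_RE = re.compile(r"<[^<>]*>")
_TABLE_CHARS = "|\t"
# retain CJK, word characters and whitespace by default
_DEFAULT_ALLOWED = re.compile(r"[^一-鿿A-Za-z0-9_\s]")


@dataclass
class Lexicon:
    """Domain dictionary: surface form -> entity category, plus stopwords.

    Surface forms may be strings (matched character-wise during
    segmentation, or as single tokens when tagging) or token tuples
    (matched as token n-grams when tagging).
    """

    entries: dict = field(default_factory=dict)
    stopwords: set = field(default_factory=set)
    min_freq: int = 5

    def __post_init__(self):
        surfaces = set(self.entries)
        if self.stopwords & {s for s in surfaces if isinstance(s, str)}:
            raise ValidationError("stopwords overlap lexicon surface forms")

    def string_entries(self) -> dict[str, str]:
        return {s: c for s, c in self.entries.items() if isinstance(s, str)}

    def ngram_entries(self) -> dict[tuple[str, ...], str]:
        out: dict[tuple[str, ...], str] = {}
        for s, c in self.entries.items():
            key = (s,) if isinstance(s, str) else tuple(s)
            if key in out and out[key] != c:
                raise ValidationError(f"surface {key!r} maps to two categories")
            out[key] = c
        return out


@dataclass
class EntityMention:
    """A tagged entity span (0-based, half-open token indices)."""

    bulletin_id: str
    start: int
    end: int
    category: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("entity span must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def bio_tags(self) -> list[str]:
        return [f"B-{self.category}"] + [f"I-{self.category}"] * (
            self.end - self.start - 1)

    def key(self) -> tuple:
        return (self.bulletin_id, self.start, self.end, self.category)


@dataclass
class TaggerEval:
    precision: float
    recall: float
    f1: float
    per_category: dict[str, dict[str, int]]


@dataclass
class FilterReport:
    tokens_before: int
    tokens_after: int
    vocab_before: int
    vocab_after: int
    removed_stopwords: int
    removed_low_freq: int


def clean_text(raw: str, allowed: re.Pattern = _DEFAULT_ALLOWED) -> str:
    """Strip markup tags, table delimiters and disallowed characters.

    Idempotent: cleaning a cleaned string is the identity.
    """
    s = _TAG_RE.sub("", raw)
    for ch in _TABLE_CHARS:
        s = s.replace(ch, " ")
    s = allowed.sub("", s)
    return s


def segment(text: str, lexicon: Lexicon) -> list[str]:
    """Greedy leftmost-longest dictionary segmentation.

    Every lexicon entry is kept intact; characters not covered by any entry
    become single-character tokens.  ``"".join(result) == text`` always.
    """
    entries = lexicon.string_entries()
    if not entries:
        raise ValidationError("lexicon has no string entries")
    max_len = max(len(s) for s in entries)
    tokens: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        match = None
        for L in range(min(max_len, n - i), 0, -1):
            cand = text[i:i + L]
            if cand in entries:
                match = cand
                break
        if match is None:
            match = text[i]
        tokens.append(match)
        i += len(match)
    return tokens


def deduplicate(corpus: Sequence[Bulletin]) -> tuple[list[Bulletin], list[dict]]:
    """Keep the first record per ID; return (kept, log of dropped records)."""
    seen: set[str] = set()
    kept: list[Bulletin] = []
    dropped: list[dict] = []
    for pos, b in enumerate(corpus):
        if b.id in seen:
            dropped.append({"id": b.id, "position": pos})
        else:
            seen.add(b.id)
            kept.append(b)
    return kept, dropped


def filter_tokens(
    docs: Sequence[Sequence[str]], lexicon: Lexicon
) -> tuple[list[list[str]], FilterReport]:
    """Remove stopwords and low-frequency tokens.

    Frequencies are counted on the raw segmented corpus, before any removal,
    so the two removals commute.
    """
    freq = Counter(tok for doc in docs for tok in doc)
    stop = lexicon.stopwords
    min_freq = lexicon.min_freq
    out = [
        [t for t in doc if t not in stop and freq[t] >= min_freq]
        for doc in docs
    ]
    before = sum(freq.values())
    after = sum(len(d) for d in out)
    kept_vocab = {t for d in out for t in d}
    removed_stop = sum(c for t, c in freq.items() if t in stop)
    removed_low = sum(
        c for t, c in freq.items() if t not in stop and c < min_freq)
    return out, FilterReport(
        tokens_before=before, tokens_after=after,
        vocab_before=len(freq), vocab_after=len(kept_vocab),
        removed_stopwords=removed_stop, removed_low_freq=removed_low,
    )


def tag_entities(
    doc: Sequence[str], lexicon: Lexicon, bulletin_id: str = ""
) -> list[EntityMention]:
    """Emit every maximal (leftmost-longest) lexicon match as a BIO mention."""
    entries = lexicon.ngram_entries()
    if not entries:
        return []
    max_len = max(len(k) for k in entries)
    mentions: list[EntityMention] = []
    i = 0
    n = len(doc)
    while i < n:
        hit = None
        for L in range(min(max_len, n - i), 0, -1):
            key = tuple(doc[i:i + L])
            if key in entries:
                hit = (L, entries[key])
                break
        if hit is None:
            i += 1
        else:
            L, cat = hit
            mentions.append(EntityMention(bulletin_id, i, i + L, cat))
            i += L
    return mentions


def evaluate_tagger(
    predicted: Iterable[EntityMention], truth: Iterable[EntityMention]
) -> TaggerEval:
    """Micro-averaged P/R/F1 with exact-span, exact-category matching."""
    pred_keys = Counter(m.key() for m in predicted)
    true_keys = Counter(m.key() for m in truth)
    cats = {k[3] for k in pred_keys} | {k[3] for k in true_keys}
    per_cat = {c: {"tp": 0, "fp": 0, "fn": 0} for c in sorted(cats)}
    tp = fp = fn = 0
    for key, np_ in pred_keys.items():
        nt = true_keys.get(key, 0)
        hit = min(np_, nt)
        per_cat[key[3]]["tp"] += hit
        per_cat[key[3]]["fp"] += np_ - hit
        tp += hit
        fp += np_ - hit
    for key, nt in true_keys.items():
        miss = nt - min(nt, pred_keys.get(key, 0))
        per_cat[key[3]]["fn"] += miss
        fn += miss
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return TaggerEval(precision=p, recall=r, f1=f1, per_category=per_cat)


def truth_mentions(bulletin: Bulletin) -> list[EntityMention]:
    """Planted entity spans as EntityMention objects (the tagger's oracle)."""
    return [
        EntityMention(bulletin.id, m["start"], m["end"], m["category"])
        for m in bulletin.truth.get("entities", [])
    ]


def lexicon_from_corpus_truth(corpus: Sequence[Bulletin], **kwargs) -> Lexicon:
    """Build the tagging lexicon from planted surfaces (the 'oracle' lexicon)."""
    entries: dict = {}
    for b in corpus:
        for m in b.truth.get("entities", []):
            key = tuple(m["surface"])
            if len(key) == 1:
                key = key[0]
            prev = entries.get(key)
            if prev is not None and prev != m["category"]:
                raise ValidationError(
                    f"surface {key!r} planted with two categories")
            entries[key] = m["category"]
    return Lexicon(entries=entries, **kwargs)
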