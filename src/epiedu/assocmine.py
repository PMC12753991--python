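"""Apriori frequent-itemset mining and association-rule induction over
bulletin-level transactions.

Supports and confidences are computed with exact integer counts (reported
as ``fractions.Fraction`` internally, floats at the surface), so the
level-wise miner can be checked against brute-force subset enumeration
without tolerance questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

from .errors import ValidationError
from .synthcorpus import Bulletin


def _exact(threshold: float) -> Fraction:
    """A float threshold like 0.3 as the exact rational it prints as."""
    return Fraction(threshold).limit_denominator(10**9)


@dataclass
class AssocConfig:
    min_support: float = 0.3
    min_confidence: float = 0.7
    max_itemset_size: int = 4

    def validate(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValidationError("min_support must be in (0, 1]")
        if not (0 < self.min_confidence <= 1):
            raise ValidationError("min_confidence must be in (0, 1]")
        if self.max_itemset_size < 1:
            raise ValidationError("max_itemset_size must be >= 1")


@dataclass(frozen=True)
class AssocRule:
    antecedent: frozenset
    consequent: frozenset
    support: Fraction
    confidence: Fraction

    def __post_init__(self):
        if not self.antecedent or not self.consequent:
            raise ValidationError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValidationError("antecedent and consequent must be disjoint")


def _as_sets(transactions: Sequence) -> list[frozenset]:
    out = []
    for t in transactions:
        items = t.items if hasattr(t, "items") and not isinstance(t, dict) \
            else t
        out.append(frozenset(items))
    return out


def transactions_from_bulletins(
    corpus: Sequence[Bulletin], use_truth: bool = True
) -> list[frozenset]:
    """Bulletin-level item sets from planted truth (or from raw tokens when
    running 'blind' on fused canonical labels)."""
    if use_truth:
        return [frozenset(b.truth.get("items", [])) for b in corpus]
    return [frozenset(b.text) for b in corpus]


def support_count(transactions: Sequence[frozenset],
                  itemset: frozenset) -> int:
    return sum(1 for t in transactions if itemset <= t)


def apriori(
    transactions: Sequence, config: AssocConfig | None = None
) -> list[tuple[frozenset, Fraction]]:
    """Exactly the itemsets (size <= max) with support >= min_support,
    mined level-wise with candidate pruning; sorted by (size, items)."""
    config = config or AssocConfig()
    config.validate()
    tx = _as_sets(transactions)
    if not tx:
        raise ValidationError("transaction list is empty")
    n = len(tx)
    min_count = _exact(config.min_support) * n

    items = sorted({i for t in tx for i in t})
    frequent: list[tuple[frozenset, Fraction]] = []
    current: list[frozenset] = []
    for it in items:
        c = support_count(tx, frozenset([it]))
        if c >= min_count:
            s = frozenset([it])
            frequent.append((s, Fraction(c, n)))
            current.append(s)

    size = 1
    while current and size < config.max_itemset_size:
        size += 1
        prev = set(current)
        candidates = set()
        for a, b in combinations(sorted(current, key=sorted), 2):
            cand = a | b
            if len(cand) != size:
                continue
            # prune: every (size-1)-subset must itself be frequent
            if all(cand - {x} in prev for x in cand):
                candidates.add(cand)
        current = []
        for cand in sorted(candidates, key=sorted):
            c = support_count(tx, cand)
            if c >= min_count:
                frequent.append((cand, Fraction(c, n)))
                current.append(cand)

    frequent.sort(key=lambda fs: (len(fs[0]), sorted(fs[0])))
    return frequent


def induce_rules(
    frequent_itemsets: Sequence[tuple[frozenset, Fraction]],
    transactions: Sequence,
    config: AssocConfig | None = None,
) -> list[AssocRule]:
    """All non-trivial antecedent/consequent splits of each frequent itemset
    whose confidence meets the floor."""
    config = config or AssocConfig()
    config.validate()
    tx = _as_sets(transactions)
    n = len(tx)
    rules: list[AssocRule] = []
    for itemset, supp in frequent_itemsets:
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                ante_fs = frozenset(ante)
                ante_count = support_count(tx, ante_fs)
                conf = Fraction(supp * n) / ante_count
                if conf >= _exact(config.min_confidence):
                    rules.append(AssocRule(
                        antecedent=ante_fs,
                        consequent=itemset - ante_fs,
                        support=supp,
                        confidence=conf,
                    ))
    rules.sort(key=lambda r: (len(r.antecedent | r.consequent),
                              sorted(r.antecedent), sorted(r.consequent)))
    return rules


def max_confidence_split(
    rules: Iterable[AssocRule], itemset: frozenset
) -> AssocRule | None:
    """Summary split of a (e.g. ternary) itemset: the highest-confidence
    rule among its splits (ties -> first in the deterministic rule order)."""
    best = None
    for r in rules:
        if (r.antecedent | r.consequent) == itemset:
            if best is None or r.confidence > best.confidence:
                best = r
    return best


def cooccurrence_conditional(transactions: Sequence, a: str, b: str) -> Fraction:
    """Directional conditional rate count(a∧b)/count(a) — identical to the
    confidence of the rule a -> b."""
    tx = _as_sets(transactions)
    n_a = sum(1 for t in tx if a in t)
    if n_a == 0:
        raise ValidationError(f"item {a!r} absent from every transaction")
    n_ab = sum(1 for t in tx if a in t and b in t)
    return Fraction(n_ab, n_a)


def brute_force_frequent(
    transactions: Sequence, config: AssocConfig | None = None
) -> list[tuple[frozenset, Fraction]]:
    """Exhaustive enumeration over all item subsets — the independent oracle
    for small instances (intended for <= ~10 distinct items)."""
    config = config or AssocConfig()
    tx = _as_sets(transactions)
    if not tx:
        raise ValidationError("transaction list is empty")
    n = len(tx)
    items = sorted({i for t in tx for i in t})
    out = []
    for size in range(1, min(len(items), config.max_itemset_size) + 1):
        for combo in combinations(items, size):
            fs = frozenset(combo)
            c = support_count(tx, fs)
            if c >= _exact(config.min_support) * n:
                out.append((fs, Fraction(c, n)))
    out.sort(key=lambda fs: (len(fs[0]), sorted(fs[0])))
    return out
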