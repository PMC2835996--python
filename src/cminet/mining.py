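"""Apriori frequent-itemset generation and association-rule extraction.

Transactions are cancer types; items are miRNAs.  A frequent itemset is a
set of miRNAs jointly dysregulated in at least a ``min_support`` fraction of
cancer types, and a rule X -> Y says: in cancers where every miRNA in X is
dysregulated, those in Y tend to be dysregulated too, with

    support(X -> Y)    = |{t : X u Y subseteq t}| / n_transactions
    confidence(X -> Y) = support(X u Y) / support(X)

Support is a fraction of transactions (raw counts are reported alongside),
so the canonical thresholds are min_support 0.3 and min_confidence 0.8.
The search is the classic two-phase algorithm: level-wise candidate
generation with subset pruning (every subset of a frequent itemset is
frequent), then consequent-growing rule generation with the anti-monotone
confidence prune.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .network import TransactionDatabase

__all__ = [
    "FrequentItemset",
    "AssociationRule",
    "support",
    "support_count",
    "confidence",
    "apriori",
    "generate_rules",
    "top_rules",
    "rules_frame",
]


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: float
    count: int

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("frequent itemset must be non-empty")


@dataclass(frozen=True)
class AssociationRule:
    """A rule X -> Y with disjoint, non-empty antecedent and consequent."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    support_count: int
    confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("both rule sides must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def __str__(self) -> str:
        lhs = ", ".join(sorted(self.antecedent))
        rhs = ", ".join(sorted(self.consequent))
        return f"{{{lhs}}} -> {{{rhs}}}"


def support_count(db: TransactionDatabase, items: Iterable[str]) -> int:
    """Number of transactions containing every item."""
    itemset = frozenset(items)
    return sum(1 for t in db.transactions.values() if itemset <= t)


def support(db: TransactionDatabase, items: Iterable[str]) -> float:
    """Fraction of transactions containing the itemset (1.0 for the empty set)."""
    if db.n_transactions == 0:
        raise ValueError("support is undefined on an empty transaction database")
    return support_count(db, items) / db.n_transactions


def confidence(
    db: TransactionDatabase,
    antecedent: Iterable[str],
    consequent: Iterable[str],
) -> float:
    """Observed conditional frequency of the consequent given the antecedent."""
    x = frozenset(antecedent)
    y = frozenset(consequent)
    n_x = support_count(db, x)
    if n_x == 0:
        raise ValueError("confidence undefined: antecedent has zero support")
    return support_count(db, x | y) / n_x


def _sorted_itemsets(itemsets: Iterable[FrequentItemset]) -> list[FrequentItemset]:
    return sorted(itemsets, key=lambda f: (len(f.items), tuple(sorted(f.items))))


def apriori(
    db: TransactionDatabase,
    min_support: float,
    max_len: int = 6,
) -> list[FrequentItemset]:
    """Level-wise frequent-itemset search.

    Returns exactly the itemsets with support >= ``min_support`` (and size
    <= ``max_len``), sorted by size then lexicographically.  Candidate
    k-itemsets are joined from frequent (k-1)-itemsets sharing a (k-2)
    prefix and pruned when any (k-1)-subset is infrequent.
    """
    if not (0 < min_support <= 1):
        raise ValueError("min_support must be in (0, 1]")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = db.n_transactions
    if n == 0:
        raise ValueError("support is undefined on an empty transaction database")
    min_count = min_support * n

    # item -> transaction-id bitmask for fast intersection counting
    tids: dict[str, int] = {}
    for t_index, itemset in enumerate(db.transactions.values()):
        for item in itemset:
            tids[item] = tids.get(item, 0) | (1 << t_index)

    def count(mask: int) -> int:
        return mask.bit_count()

    result: list[FrequentItemset] = []
    current: dict[tuple[str, ...], int] = {}  # sorted items -> tid mask
    for item in sorted(tids):
        mask = tids[item]
        if count(mask) >= min_count:
            current[(item,)] = mask
            result.append(FrequentItemset(frozenset((item,)), count(mask) / n, count(mask)))

    k = 1
    while current and k < max_len:
        frequent_keys = set(current)
        nxt: dict[tuple[str, ...], int] = {}
        keys = sorted(current)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: once prefixes diverge, no later match
                candidate = a + (b[-1],)
                # subset prune: every (k)-subset must itself be frequent
                if any(
                    candidate[:j] + candidate[j + 1 :] not in frequent_keys
                    for j in range(len(candidate) - 2)
                ):
                    continue
                mask = current[a] & current[b]
                c = count(mask)
                if c >= min_count:
                    nxt[candidate] = mask
                    result.append(FrequentItemset(frozenset(candidate), c / n, c))
        current = nxt
        k += 1
    return _sorted_itemsets(result)


def generate_rules(
    frequent: Sequence[FrequentItemset],
    db: TransactionDatabase,
    min_confidence: float,
) -> list[AssociationRule]:
    """Extract all rules X -> Y with confidence >= ``min_confidence``.

    For each frequent itemset of size >= 2, high-confidence rules with a
    single-item consequent are extracted first; candidate consequents are
    then grown by merging consequents of surviving rules.  Because
    confidence(X -> Y) is anti-monotone in Y (for fixed X u Y), any
    consequent whose subset already failed the threshold is pruned.
    """
    if not (0 < min_confidence <= 1):
        raise ValueError("min_confidence must be in (0, 1]")
    counts = {f.items: f.count for f in frequent}
    n = db.n_transactions
    rules: list[AssociationRule] = []

    def cnt(items: frozenset[str]) -> int:
        c = counts.get(items)
        if c is None:  # subset of a frequent itemset is frequent; count on demand
            c = support_count(db, items)
            counts[items] = c
        return c

    for f in frequent:
        if len(f.items) < 2:
            continue
        itemset = f.items
        whole = f.count
        # consequents of size 1 first, then grown level-wise
        consequents = [frozenset((i,)) for i in sorted(itemset)]
        while consequents:
            surviving: list[frozenset[str]] = []
            for y in consequents:
                x = itemset - y
                if not x:
                    continue
                conf = whole / cnt(x)
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(x, y, whole / n, whole, conf)
                    )
                    surviving.append(y)
            consequents = _grow_consequents(surviving, itemset)
    rules.sort(
        key=lambda r: (
            tuple(sorted(r.items)),
            len(r.consequent),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def _grow_consequents(
    survivors: list[frozenset[str]], itemset: frozenset[str]
) -> list[frozenset[str]]:
    """Merge size-k surviving consequents into size-(k+1) candidates."""
    if not survivors:
        return []
    k = len(survivors[0])
    if k + 1 >= len(itemset):
        return []
    survivor_set = set(survivors)
    out: set[frozenset[str]] = set()
    for a, b in combinations(survivors, 2):
        merged = a | b
        if len(merged) != k + 1:
            continue
        # anti-monotone prune: every k-subset must have survived
        if all(merged - {i} in survivor_set for i in merged):
            out.add(merged)
    return sorted(out, key=lambda s: tuple(sorted(s)))


def top_rules(rules: Sequence[AssociationRule], k: int) -> list[AssociationRule]:
    """First ``k`` rules under (confidence desc, support desc, size desc, lex).

    The ordering is total, so the result is independent of input order.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ranked = sorted(
        rules,
        key=lambda r: (
            -r.confidence,
            -r.support,
            -len(r.items),
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        ),
    )
    return ranked[:k]


def rules_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Tabular report of rules in the `{X} -> {Y}` notation."""
    return pd.DataFrame(
        {
            "antecedent": ["{" + ", ".join(sorted(r.antecedent)) + "}" for r in rules],
            "consequent": ["{" + ", ".join(sorted(r.consequent)) + "}" for r in rules],
            "support_fraction": [r.support for r in rules],
            "support_count": [r.support_count for r in rules],
            "confidence": [r.confidence for r in rules],
        }
    )
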