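"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (powerset enumeration, exhaustive
hypergeometric sums, pairwise union-find) that share no code with the
package paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import chain, combinations
from math import comb


def powerset_frequent(transactions: dict, min_support: float) -> dict:
    """All frequent itemsets by full powerset enumeration.

    Returns {frozenset: support fraction}.
    """
    items = sorted(set().union(*transactions.values()) if transactions else set())
    n = len(transactions)
    out = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions.values() if s <= t)
            if count / n >= min_support:
                out[s] = count / n
    return out


def partition_rules(transactions: dict, min_support: float, min_confidence: float):
    """All rules X -> Y by exhaustive partition enumeration.

    Returns {(frozenset X, frozenset Y): (support, confidence)} over every
    frequent itemset and every non-trivial bipartition of it.
    """
    frequent = powerset_frequent(transactions, min_support)
    n = len(transactions)

    def count(s):
        return sum(1 for t in transactions.values() if s <= t)

    out = {}
    for itemset in frequent:
        if len(itemset) < 2:
            continue
        whole = count(itemset)
        members = sorted(itemset)
        for r in range(1, len(members)):
            for x_tuple in combinations(members, r):
                x = frozenset(x_tuple)
                y = itemset - x
                conf = whole / count(x)
                if conf >= min_confidence:
                    out[(x, y)] = (whole / n, conf)
    return out


def hypergeom_pmf(a: int, row1: int, col1: int, total: int) -> Fraction:
    """Exact P(X = a) for a 2x2 table with the given fixed margins."""
    return Fraction(comb(row1, a) * comb(total - row1, col1 - a), comb(total, col1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact test by exhaustive enumeration over fixed margins.

    Point-probability rule: sum the probabilities of every table (with the
    observed margins) whose probability does not exceed the observed
    table's.  Exact rational arithmetic, so ties are handled exactly.
    """
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    p_obs = hypergeom_pmf(a, row1, col1, total)
    p = Fraction(0)
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, col1, total)
        if pk <= p_obs:
            p += pk
    return float(min(p, Fraction(1)))


def fisher_one_sided(a: int, b: int, c: int, d: int, alternative: str) -> float:
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    ks = range(a, hi + 1) if alternative == "greater" else range(lo, a + 1)
    return float(min(sum(hypergeom_pmf(k, row1, col1, total) for k in ks), Fraction(1)))


def pairwise_gap_clusters(loci, max_gap: int):
    """Connected components of the pairwise gap <= max_gap relation.

    Union-find over ALL same-chromosome locus pairs, with the gap of a pair
    defined as max(0, later.start - earlier.end) after ordering by start.
    Returns a set of frozensets of member names (components of size >= 2).
    """
    parent = {l.mirna: l.mirna for l in loci}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            if a.chrom != b.chrom:
                continue
            first, second = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
            gap = max(0, second.start - first.end)
            if gap <= max_gap:
                union(a.mirna, b.mirna)
    comps: dict[str, set[str]] = {}
    for l in loci:
        comps.setdefault(find(l.mirna), set()).add(l.mirna)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def brute_codysregulation(network, cluster_members, direction):
    """Fraction of cancers with a same-cluster, same-direction member pair.

    Triple loop over (cancer, cluster, member pair); no early exits.
    """
    positives = 0
    for cancer in network.cancers:
        adj = network.mirnas_of(cancer)
        hit = False
        for members in cluster_members:
            for m1, m2 in combinations(sorted(members), 2):
                if adj.get(m1) is direction and adj.get(m2) is direction:
                    hit = True
        if hit:
            positives += 1
    return positives / len(network.cancers)


def all_tables_with_total_at_most(n_max: int):
    """Every 2x2 count table (a, b, c, d) with 1 <= a+b+c+d <= n_max."""
    for total in range(1, n_max + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    yield a, b, c, total - a - b - c


def canonical_table(t):
    """Representative of a table's orbit under row swap, column swap, transpose.

    All three operations leave the two-sided exact-test p-value unchanged.
    """
    a, b, c, d = t
    return min(
        (a, b, c, d),
        (c, d, a, b),
        (b, a, d, c),
        (d, c, b, a),
        (a, c, b, d),
        (b, d, a, c),
        (c, a, d, b),
        (d, b, c, a),
    )
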