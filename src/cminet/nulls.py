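"""Degree-preserving randomization nulls and empirical permutation p-values.

Two rewiring modes are provided:

``cancer-degree`` (default)
    For each cancer independently, its d partner miRNAs are resampled
    uniformly without replacement from the full miRNA set, and the cancer's
    original multiset of edge signs is reattached to the new partners in
    shuffled order.  Every cancer's degree is preserved exactly; miRNA
    degrees are free to vary (they must be, or hub significance would be
    vacuous).

``double-swap``
    Classic bipartite double edge swaps (c1-m1, c2-m2) -> (c1-m2, c2-m1),
    each edge keeping its sign, rejecting swaps that would create duplicate
    pairs.  Preserves BOTH degree sequences exactly; offered as a stricter
    sensitivity-analysis null.

Empirical p-values use the add-one (pseudo-count) estimator
p = (b + 1)/(n + 1), where b null replicates are at least as extreme as the
observed statistic; with n replicates the p-value is floored at 1/(n + 1)
and that floor is part of the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network import Direction, DysregulationEdge, SignedBipartiteNetwork

__all__ = [
    "EmpiricalPValue",
    "Statistic",
    "mirna_degree_statistic",
    "rule_support_statistic",
    "cluster_codysregulation_statistic",
    "rewire_cancer_degree_preserving",
    "double_edge_swap",
    "empirical_pvalue",
    "permutation_test",
    "derive_seed",
]

_SIGN_UP = 1
_SIGN_DOWN = 0


@dataclass(frozen=True)
class EmpiricalPValue:
    """Result of a randomization test, with full provenance."""

    observed: float
    n_replicates: int
    n_as_extreme: int
    p: float
    tail: str  # "upper" | "lower"
    seed: int | None = None
    mode: str | None = None
    statistic: str | None = None

    @property
    def p_floor(self) -> float:
        """Smallest p-value reportable at this replicate count."""
        return 1.0 / (self.n_replicates + 1)


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic sub-seed for a named test, below 2**31.

    Derived from (master seed, test name) so adding tests to a pipeline
    never perturbs the substreams of existing ones.
    """
    import hashlib

    h = hashlib.blake2b(f"{master_seed}:{name}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**31)


# -- compact array representation -----------------------------------------
#
# Permutation tests rewire thousands of networks; rebuilding full
# SignedBipartiteNetwork objects per replicate would dominate the runtime.
# The compact form keeps, per cancer, an int array of partner miRNA indices
# and a parallel 0/1 sign array.


@dataclass
class _Compact:
    cancers: tuple[str, ...]
    mirnas: tuple[str, ...]
    mirna_index: dict[str, int]
    partners: list[np.ndarray]  # per cancer, miRNA indices
    signs: list[np.ndarray]  # per cancer, 1=UP 0=DOWN

    @classmethod
    def from_network(cls, network: SignedBipartiteNetwork) -> "_Compact":
        mirna_index = {m: i for i, m in enumerate(network.mirnas)}
        partners, signs = [], []
        for c in network.cancers:
            adj = network.mirnas_of(c)
            idx = np.fromiter(
                (mirna_index[m] for m in adj), dtype=np.int64, count=len(adj)
            )
            sgn = np.fromiter(
                (_SIGN_UP if d is Direction.UP else _SIGN_DOWN for d in adj.values()),
                dtype=np.int8,
                count=len(adj),
            )
            partners.append(idx)
            signs.append(sgn)
        return cls(network.cancers, network.mirnas, mirna_index, partners, signs)

    def to_network(self) -> SignedBipartiteNetwork:
        edges = []
        for ci, c in enumerate(self.cancers):
            for m_idx, s in zip(self.partners[ci], self.signs[ci]):
                edges.append(
                    DysregulationEdge(
                        c,
                        self.mirnas[m_idx],
                        Direction.UP if s == _SIGN_UP else Direction.DOWN,
                    )
                )
        return SignedBipartiteNetwork(self.cancers, self.mirnas, edges)

    def rewire_cancer_degree(self, rng: np.random.Generator) -> "_Compact":
        n_m = len(self.mirnas)
        new_partners, new_signs = [], []
        for idx, sgn in zip(self.partners, self.signs):
            d = len(idx)
            if d > n_m:
                raise ValueError(
                    f"cancer degree {d} exceeds miRNA count {n_m}: rewiring infeasible"
                )
            new_partners.append(rng.choice(n_m, size=d, replace=False))
            new_signs.append(rng.permutation(sgn) if d else sgn.copy())
        return _Compact(
            self.cancers, self.mirnas, self.mirna_index, new_partners, new_signs
        )

    def rewire_double_swap(
        self, n_swaps: int, rng: np.random.Generator, max_attempts: int | None = None
    ) -> "_Compact":
        # flat edge arrays
        c_idx = np.concatenate(
            [np.full(len(p), i, dtype=np.int64) for i, p in enumerate(self.partners)]
        ) if self.partners else np.empty(0, dtype=np.int64)
        m_idx = (
            np.concatenate(self.partners)
            if self.partners
            else np.empty(0, dtype=np.int64)
        )
        s_arr = (
            np.concatenate(self.signs) if self.signs else np.empty(0, dtype=np.int8)
        )
        n_edges = len(m_idx)
        if n_edges < 2:
            raise ValueError("double edge swap needs at least 2 edges")
        present = {(int(c), int(m)) for c, m in zip(c_idx, m_idx)}
        if max_attempts is None:
            max_attempts = 100 * max(n_swaps, 1) + 1000
        accepted = attempts = 0
        while accepted < n_swaps and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, n_edges, size=2)
            if i == j:
                continue
            c1, m1 = int(c_idx[i]), int(m_idx[i])
            c2, m2 = int(c_idx[j]), int(m_idx[j])
            if c1 == c2 or m1 == m2:
                continue
            if (c1, m2) in present or (c2, m1) in present:
                continue
            present.discard((c1, m1))
            present.discard((c2, m2))
            present.add((c1, m2))
            present.add((c2, m1))
            m_idx[i], m_idx[j] = m2, m1
            accepted += 1
        new_partners, new_signs = [], []
        for i in range(len(self.cancers)):
            mask = c_idx == i
            new_partners.append(m_idx[mask].copy())
            new_signs.append(s_arr[mask].copy())
        return _Compact(
            self.cancers, self.mirnas, self.mirna_index, new_partners, new_signs
        )


# -- statistics ------------------------------------------------------------


@dataclass(frozen=True)
class Statistic:
    """A named network statistic usable in :func:`permutation_test`.

    ``evaluate`` receives the compact representation so the statistic can be
    recomputed cheaply on every rewired replicate.
    """

    name: str
    evaluate: Callable[[_Compact], float] = field(compare=False)


def mirna_degree_statistic(mirna: str) -> Statistic:
    """Degree (number of associated cancer types) of one miRNA."""

    def ev(compact: _Compact) -> float:
        mi = compact.mirna_index[mirna]
        return float(sum(int((p == mi).sum() > 0) for p in compact.partners))

    return Statistic(f"mirna-degree({mirna})", ev)


def rule_support_statistic(items: Sequence[str]) -> Statistic:
    """Support count of an itemset: cancers containing every listed miRNA."""
    names = tuple(sorted(set(items)))

    def ev(compact: _Compact) -> float:
        idx = np.array([compact.mirna_index[m] for m in names], dtype=np.int64)
        count = 0
        for p in compact.partners:
            if len(p) >= len(idx) and np.isin(idx, p).all():
                count += 1
        return float(count)

    return Statistic(f"rule-support-count({{{', '.join(names)}}})", ev)


def cluster_codysregulation_statistic(
    clusters: Sequence[Sequence[str]], direction: Direction
) -> Statistic:
    """Fraction of cancers with >= 2 same-cluster miRNAs in the given direction.

    ``clusters`` is a sequence of member-label groups (e.g. from
    :func:`cminet.clusters.build_clusters`); members absent from the network
    simply cannot contribute.
    """
    want = _SIGN_UP if direction is Direction.UP else _SIGN_DOWN
    member_lists = [tuple(c) for c in clusters]

    def ev(compact: _Compact) -> float:
        if not compact.cancers:
            return 0.0
        cluster_idx = [
            [compact.mirna_index[m] for m in members if m in compact.mirna_index]
            for members in member_lists
        ]
        n_m = len(compact.mirnas)
        sign_of = np.full(n_m, -1, dtype=np.int8)
        positive = 0
        for p, s in zip(compact.partners, compact.signs):
            sign_of[p] = s
            for members in cluster_idx:
                hits = 0
                for mi in members:
                    if sign_of[mi] == want:
                        hits += 1
                        if hits >= 2:
                            break
                if hits >= 2:
                    positive += 1
                    break
            sign_of[p] = -1  # reset touched entries only
        return positive / len(compact.cancers)

    return Statistic(f"cluster-codysregulation-fraction({direction.value})", ev)


def total_edge_count_statistic() -> Statistic:
    """Total edge count; constant under any degree-preserving rewiring."""
    return Statistic(
        "total-edge-count",
        lambda compact: float(sum(len(p) for p in compact.partners)),
    )


# -- rewiring (public, whole-network) --------------------------------------


def rewire_cancer_degree_preserving(
    network: SignedBipartiteNetwork, rng: np.random.Generator
) -> SignedBipartiteNetwork:
    """One cancer-degree-preserving rewiring of the whole network.

    Edge evidence is dropped (a rewired edge asserts nothing about any
    publication).  Deterministic for a given generator state.
    """
    return _Compact.from_network(network).rewire_cancer_degree(rng).to_network()


def double_edge_swap(
    network: SignedBipartiteNetwork,
    n_swaps: int,
    rng: np.random.Generator,
) -> SignedBipartiteNetwork:
    """Randomize by ``n_swaps`` accepted sign-preserving double edge swaps."""
    return _Compact.from_network(network).rewire_double_swap(n_swaps, rng).to_network()


# -- empirical p-values ----------------------------------------------------


def empirical_pvalue(
    observed: float,
    null_values: Sequence[float],
    tail: str = "upper",
    seed: int | None = None,
    mode: str | None = None,
    statistic: str | None = None,
) -> EmpiricalPValue:
    """Add-one empirical p-value of ``observed`` against null replicates."""
    if tail not in {"upper", "lower"}:
        raise ValueError(f"unknown tail {tail!r}")
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("null_values must be non-empty")
    if tail == "upper":
        b = int((nulls >= observed).sum())
    else:
        b = int((nulls <= observed).sum())
    n = int(nulls.size)
    return EmpiricalPValue(
        observed=float(observed),
        n_replicates=n,
        n_as_extreme=b,
        p=(b + 1) / (n + 1),
        tail=tail,
        seed=seed,
        mode=mode,
        statistic=statistic,
    )


def permutation_test(
    network: SignedBipartiteNetwork,
    statistic: Statistic,
    n_replicates: int = 1000,
    rewire_mode: str = "cancer-degree",
    tail: str = "upper",
    seed: int = 0,
    n_swaps_per_replicate: int | None = None,
) -> EmpiricalPValue:
    """Randomization test of a network statistic.

    The observed statistic is compared against its value on ``n_replicates``
    independent rewirings (each drawn fresh from the input network).  With
    ``double-swap`` mode, each replicate applies 10x|E| accepted swaps by
    default.
    """
    if rewire_mode not in {"cancer-degree", "double-swap"}:
        raise ValueError(f"unknown rewire_mode {rewire_mode!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    compact = _Compact.from_network(network)
    observed = statistic.evaluate(compact)
    rng = np.random.default_rng(seed)
    if n_swaps_per_replicate is None:
        n_swaps_per_replicate = 10 * max(network.n_edges, 1)
    nulls = np.empty(n_replicates, dtype=float)
    for r in range(n_replicates):
        if rewire_mode == "cancer-degree":
            rewired = compact.rewire_cancer_degree(rng)
        else:
            rewired = compact.rewire_double_swap(n_swaps_per_replicate, rng)
        nulls[r] = statistic.evaluate(rewired)
    return empirical_pvalue(
        observed,
        nulls,
        tail=tail,
        seed=seed,
        mode=rewire_mode,
        statistic=statistic.name,
    )
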