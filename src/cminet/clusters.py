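"""Genomic miRNA neighbor clusters and the co-dysregulation statistic.

miRNAs whose loci lie within 50 kb of each other on the same chromosome
form a genomic cluster ("neighboring miRNAs"); such groups are often
transcribed together and are therefore expected to be co-dysregulated.
Clusters are built by single-linkage chaining: consecutive loci (sorted by
start) are joined whenever the inter-locus gap max(0, next.start - prev.end)
is at most ``max_gap``; maximal chains of two or more loci are kept.

The co-dysregulation statistic asks, per cancer type, whether ANY cluster
contributes >= 2 members dysregulated in the same direction in that cancer;
the reported fraction is (#positive cancers)/(#cancers).  Its significance
is assessed with the cancer-degree-preserving randomization null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .network import Direction, GenomicLocus, SignedBipartiteNetwork
from . import nulls

__all__ = [
    "NeighborCluster",
    "build_clusters",
    "co_dysregulation_fraction",
    "cluster_coexpression_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborCluster:
    """A maximal single-linkage chain of >= 2 loci on one chromosome."""

    members: frozenset[str]
    chrom: str
    span: tuple[int, int]  # (min start, max end), 1-based inclusive

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a neighbor cluster needs >= 2 members")


def _gap(prev: GenomicLocus, nxt: GenomicLocus) -> int:
    return max(0, nxt.start - prev.end)


def build_clusters(
    loci: Sequence[GenomicLocus],
    max_gap: int = 50_000,
    strand_aware: bool = False,
    distance: str = "gap",
) -> list[NeighborCluster]:
    """Single-linkage clustering of loci at an inter-locus gap threshold.

    Parameters
    ----------
    loci
        miRNA loci; duplicate miRNA names are an error.
    max_gap
        Maximum allowed gap (bp) between consecutive loci; default 50 kb.
        Overlapping loci have gap 0.
    strand_aware
        Chain within each strand separately (default: strand-agnostic).
    distance
        ``gap`` (end-to-start, default) or ``start`` (start-to-start).

    Clustering is invariant to input order, and raising ``max_gap`` can only
    merge clusters, never split them.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if distance not in {"gap", "start"}:
        raise ValueError(f"unknown distance {distance!r}")
    names = [l.mirna for l in loci]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate miRNA loci: {dupes}")
    groups: dict[tuple, list[GenomicLocus]] = {}
    for loc in loci:
        key = (loc.chrom, loc.strand) if strand_aware else (loc.chrom,)
        groups.setdefault(key, []).append(loc)
    clusters: list[NeighborCluster] = []
    for key in sorted(groups):
        chain: list[GenomicLocus] = []
        chain_max_end = 0  # running max end: handles nested/overlapping loci
        for loc in sorted(groups[key], key=lambda l: (l.start, l.end, l.mirna)):
            if chain:
                if distance == "gap":
                    d = max(0, loc.start - chain_max_end)
                else:
                    d = loc.start - chain[-1].start
                if d <= max_gap:
                    chain.append(loc)
                    chain_max_end = max(chain_max_end, loc.end)
                    continue
                _flush(chain, clusters)
                chain = []
            chain.append(loc)
            chain_max_end = loc.end
        _flush(chain, clusters)
    clusters.sort(key=lambda c: (c.chrom, c.span))
    return clusters


def _flush(chain: list[GenomicLocus], out: list[NeighborCluster]) -> None:
    if len(chain) >= 2:
        out.append(
            NeighborCluster(
                members=frozenset(l.mirna for l in chain),
                chrom=chain[0].chrom,
                span=(min(l.start for l in chain), max(l.end for l in chain)),
            )
        )


def co_dysregulation_fraction(
    network: SignedBipartiteNetwork,
    clusters: Sequence[NeighborCluster],
    direction: Direction,
) -> tuple[float, dict[str, NeighborCluster]]:
    """Fraction of cancers with >= 2 same-cluster miRNAs in one direction.

    A cancer counts as positive iff some single cluster has at least two
    members each linked to that cancer with the given direction.  Returns
    the fraction over all cancer nodes plus, per positive cancer, one
    witnessing cluster.

    Cluster members without edges (or network miRNAs without loci) are
    allowed; they simply cannot contribute.  A completeness warning is
    logged with the counts.
    """
    if not clusters:
        raise ValueError("empty cluster list")
    mirna_set = set(network.mirnas)
    clustered = set().union(*(c.members for c in clusters))
    missing = clustered - mirna_set
    if missing:
        logger.warning(
            "%d of %d clustered miRNAs have no edges in the network",
            len(missing),
            len(clustered),
        )
    witnesses: dict[str, NeighborCluster] = {}
    for cancer in network.cancers:
        adj = network.mirnas_of(cancer)
        for cluster in clusters:
            hits = sum(1 for m in cluster.members if adj.get(m) is direction)
            if hits >= 2:
                witnesses[cancer] = cluster
                break
    n_cancers = len(network.cancers)
    fraction = len(witnesses) / n_cancers if n_cancers else 0.0
    return fraction, witnesses


def cluster_coexpression_test(
    network: SignedBipartiteNetwork,
    clusters: Sequence[NeighborCluster],
    direction: Direction,
    n_replicates: int = 1000,
    seed: int = 0,
    rewire_mode: str = "cancer-degree",
) -> nulls.EmpiricalPValue:
    """Randomization test of the co-dysregulation fraction.

    Rewiring preserves each cancer's degree and its own multiset of edge
    signs, so the null keeps per-tissue sign composition while destroying
    the genomic pairing.
    """
    if not clusters:
        raise ValueError("empty cluster list")
    statistic = nulls.cluster_codysregulation_statistic(
        [sorted(c.members) for c in clusters], direction
    )
    return nulls.permutation_test(
        network,
        statistic,
        n_replicates=n_replicates,
        rewire_mode=rewire_mode,
        tail="upper",
        seed=seed,
    )
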