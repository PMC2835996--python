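"""Seeded synthetic cancer-miRNA networks and loci with planted ground truth.

The generator emulates the statistical structure of a literature-curated
dysregulation network at its natural scale — on the order of 30 cancer
types and 200 dysregulated miRNAs — so that every pipeline stage can be
exercised and validated without any external download:

* sparse background edges at a per-pair density, with per-cancer sign bias,
* planted frequent itemsets (modules): k cancers sharing all m module
  miRNAs with a fixed direction pattern,
* planted high-degree miRNAs (hubs), optionally sign-homogeneous,
* planted genomically neighboring miRNA pairs (< 50 kb apart) whose signs
  are correlated within each cancer,
* loci for all remaining miRNAs placed with pairwise gaps > 50 kb so the
  no-cluster background stays clean.

Plants overwrite background edges rather than adding with conflict, so the
emitted :class:`GroundTruth` is exact; consistency is checked at generation
time.  Everything is deterministic for a fixed seed.

Planted miRNA identities are allocated deterministically from the label
space (modules from the front, hubs after them, cluster pairs from the
tail), so `generate_network` and `generate_loci` built from the same spec
agree on which miRNAs are the planted neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .network import (
    Direction,
    DysregulationEdge,
    GenomicLocus,
    SignedBipartiteNetwork,
)

__all__ = [
    "PlantedModule",
    "PlantedHub",
    "SyntheticSpec",
    "GroundTruth",
    "generate_network",
    "generate_loci",
]


@dataclass(frozen=True)
class PlantedModule:
    """A frequent itemset planted into k transactions.

    ``pattern`` is a string over {U, D} of length ``size`` (the direction of
    each module miRNA, identical across the k cancers), or ``None`` to draw
    one direction per miRNA at generation time.
    """

    size: int
    k: int
    pattern: str | None = None


@dataclass(frozen=True)
class PlantedHub:
    degree: int
    homogeneity: str = "up"  # "up" | "down" | "mixed"


@dataclass(frozen=True)
class SyntheticSpec:
    n_cancers: int = 30
    n_mirnas: int = 200
    background_density: float = 0.05
    sign_bias: float | Sequence[float] = 0.5  # P(edge is UP), scalar or per cancer
    planted_modules: tuple[PlantedModule, ...] = ()
    planted_hubs: tuple[PlantedHub, ...] = ()
    planted_cluster_pairs: int = 0
    cluster_rho: float = 0.9  # within-cancer sign agreement of a planted pair
    pair_edge_prob: float = 0.3  # P(a planted pair is co-reported in a cancer)
    chrom_count: int = 5
    locus_length: int = 80  # bp, typical precursor scale
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancers < 1 or self.n_mirnas < 1:
            raise ValueError("need at least one cancer and one miRNA")
        if not (0.0 <= self.background_density <= 1.0):
            raise ValueError("background_density must be in [0, 1]")
        biases = self.sign_biases()
        if any(not (0.0 <= b <= 1.0) for b in biases):
            raise ValueError("sign_bias values must be in [0, 1]")
        if not (0.0 <= self.cluster_rho <= 1.0):
            raise ValueError("cluster_rho must be in [0, 1]")
        if not (0.0 <= self.pair_edge_prob <= 1.0):
            raise ValueError("pair_edge_prob must be in [0, 1]")
        if self.chrom_count < 1:
            raise ValueError("chrom_count must be >= 1")
        for mod in self.planted_modules:
            if mod.size < 1 or mod.size > self.n_mirnas:
                raise ValueError(f"module size {mod.size} infeasible")
            if mod.k < 1 or mod.k > self.n_cancers:
                raise ValueError(f"module transaction count {mod.k} infeasible")
            if mod.pattern is not None and (
                len(mod.pattern) != mod.size or set(mod.pattern) - {"U", "D"}
            ):
                raise ValueError(f"bad module pattern {mod.pattern!r}")
        for hub in self.planted_hubs:
            if hub.degree < 1 or hub.degree > self.n_cancers:
                raise ValueError(f"hub degree {hub.degree} infeasible")
            if hub.homogeneity not in {"up", "down", "mixed"}:
                raise ValueError(f"bad hub homogeneity {hub.homogeneity!r}")
        n_reserved = (
            sum(m.size for m in self.planted_modules)
            + len(self.planted_hubs)
            + 2 * self.planted_cluster_pairs
        )
        if n_reserved > self.n_mirnas:
            raise ValueError(
                f"plants need {n_reserved} distinct miRNAs but only "
                f"{self.n_mirnas} exist"
            )

    def sign_biases(self) -> list[float]:
        if isinstance(self.sign_bias, (int, float)):
            return [float(self.sign_bias)] * self.n_cancers
        biases = [float(b) for b in self.sign_bias]
        if len(biases) != self.n_cancers:
            raise ValueError("per-cancer sign_bias list length != n_cancers")
        return biases

    # deterministic label space -------------------------------------------

    def cancer_labels(self) -> list[str]:
        return [f"cancer-{i:02d}" for i in range(self.n_cancers)]

    def mirna_labels(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(self.n_mirnas)]

    def module_mirnas(self) -> list[list[str]]:
        labels = self.mirna_labels()
        out, cursor = [], 0
        for mod in self.planted_modules:
            out.append(labels[cursor : cursor + mod.size])
            cursor += mod.size
        return out

    def hub_mirnas(self) -> list[str]:
        cursor = sum(m.size for m in self.planted_modules)
        return self.mirna_labels()[cursor : cursor + len(self.planted_hubs)]

    def cluster_pair_mirnas(self) -> list[tuple[str, str]]:
        labels = self.mirna_labels()
        pairs = []
        for i in range(self.planted_cluster_pairs):
            a = labels[self.n_mirnas - 2 * (i + 1)]
            b = labels[self.n_mirnas - 2 * (i + 1) + 1]
            pairs.append((a, b))
        return pairs


@dataclass
class GroundTruth:
    """Exactly what was planted, with the edges each plant created."""

    modules: list[dict] = field(default_factory=list)
    hubs: list[dict] = field(default_factory=list)
    cluster_pairs: list[dict] = field(default_factory=list)
    loci: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _sign_to_dir(up: bool) -> Direction:
    return Direction.UP if up else Direction.DOWN


def generate_network(
    spec: SyntheticSpec,
) -> tuple[SignedBipartiteNetwork, GroundTruth]:
    """Draw one synthetic network and its exact ground truth.

    Sampling order (background, then modules, hubs, cluster pairs) is fixed
    so a given seed always yields the same network.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cancers = spec.cancer_labels()
    mirnas = spec.mirna_labels()
    biases = spec.sign_biases()
    n_c, n_m = spec.n_cancers, spec.n_mirnas

    # background: independent per-pair edges, per-cancer sign bias
    present = rng.random((n_c, n_m)) < spec.background_density
    up = rng.random((n_c, n_m)) < np.asarray(biases)[:, None]
    truth = GroundTruth()

    # planted modules overwrite background
    for mod, members in zip(spec.planted_modules, spec.module_mirnas()):
        chosen = rng.choice(n_c, size=mod.k, replace=False)
        if mod.pattern is None:
            pattern = "".join(rng.choice(["U", "D"], size=mod.size))
        else:
            pattern = mod.pattern
        edges_made = []
        for ci in chosen:
            for m_label, p in zip(members, pattern):
                mi = mirnas.index(m_label)
                present[ci, mi] = True
                up[ci, mi] = p == "U"
                edges_made.append([cancers[ci], m_label, "up" if p == "U" else "down"])
        truth.modules.append(
            {
                "mirnas": list(members),
                "cancers": [cancers[ci] for ci in sorted(chosen)],
                "pattern": pattern,
                "edges": edges_made,
            }
        )

    # planted hubs: top the miRNA's degree up to target
    for hub, m_label in zip(spec.planted_hubs, spec.hub_mirnas()):
        mi = mirnas.index(m_label)
        have = np.flatnonzero(present[:, mi])
        need = hub.degree - len(have)
        if need > 0:
            free = np.setdiff1d(np.arange(n_c), have)
            extra = rng.choice(free, size=need, replace=False)
            present[extra, mi] = True
        owners = np.flatnonzero(present[:, mi])
        if hub.homogeneity == "up":
            up[owners, mi] = True
        elif hub.homogeneity == "down":
            up[owners, mi] = False
        truth.hubs.append(
            {
                "mirna": m_label,
                "degree": int(len(owners)),
                "homogeneity": hub.homogeneity,
                "edges": [
                    [cancers[ci], m_label, "up" if up[ci, mi] else "down"]
                    for ci in owners
                ],
            }
        )

    # planted genomic pairs with correlated within-cancer signs
    for a_label, b_label in spec.cluster_pair_mirnas():
        ai, bi = mirnas.index(a_label), mirnas.index(b_label)
        edges_made = []
        for ci in range(n_c):
            if rng.random() >= spec.pair_edge_prob:
                continue
            a_up = rng.random() < biases[ci]
            b_up = a_up if rng.random() < spec.cluster_rho else not a_up
            present[ci, ai] = True
            present[ci, bi] = True
            up[ci, ai] = a_up
            up[ci, bi] = b_up
            edges_made.append(
                [cancers[ci], "up" if a_up else "down", "up" if b_up else "down"]
            )
        truth.cluster_pairs.append(
            {
                "mirnas": [a_label, b_label],
                "rho": spec.cluster_rho,
                "edges": edges_made,
            }
        )

    edges = [
        DysregulationEdge(cancers[ci], mirnas[mi], _sign_to_dir(bool(up[ci, mi])))
        for ci, mi in zip(*np.nonzero(present))
    ]
    network = SignedBipartiteNetwork(cancers, mirnas, edges)
    _check_truth(network, truth)
    return network, truth


def _check_truth(network: SignedBipartiteNetwork, truth: GroundTruth) -> None:
    """Generation-time consistency check: every planted edge really exists."""
    for mod in truth.modules:
        for cancer, mirna, direction in mod["edges"]:
            assert network.direction(cancer, mirna).value == direction
    for hub in truth.hubs:
        assert network.degree(hub["mirna"]) == hub["degree"]
        for cancer, mirna, direction in hub["edges"]:
            assert network.direction(cancer, mirna).value == direction


def generate_loci(spec: SyntheticSpec) -> tuple[list[GenomicLocus], GroundTruth]:
    """Place miRNA loci: planted pairs < 50 kb apart, the rest > 50 kb apart.

    Non-planted miRNAs are placed uniformly on each chromosome with a
    rejection check enforcing pairwise gaps > 50 kb; planted pair members
    sit at gaps drawn uniformly in [1, 45000] bp.  Loci are 80 bp long
    (typical precursor scale).

    Raises a generation error if the spacing cannot be satisfied within the
    attempt budget (the synthetic genome is sized generously to avoid this).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # independent of network stream
    pair_members = spec.cluster_pair_mirnas()
    paired = {m for pair in pair_members for m in pair}
    singles = [m for m in spec.mirna_labels() if m not in paired]
    length = spec.locus_length
    min_gap = 50_000

    # chromosome assignment: round-robin placement units (singles and pairs)
    units: list[tuple[str, ...]] = [(m,) for m in singles] + [
        tuple(p) for p in pair_members
    ]
    per_chrom: dict[str, list[tuple[str, ...]]] = {
        f"chr{c + 1}": [] for c in range(spec.chrom_count)
    }
    chrom_names = list(per_chrom)
    for i, unit in enumerate(units):
        per_chrom[chrom_names[i % len(chrom_names)]].append(unit)

    loci: list[GenomicLocus] = []
    truth = GroundTruth()
    for chrom, chrom_units in per_chrom.items():
        n_units = len(chrom_units)
        if n_units == 0:
            continue
        genome_len = max(1_000_000, n_units * 3_000_000)
        for attempt in range(200):
            starts = np.sort(rng.integers(1, genome_len, size=n_units))
            # unit footprint ~ locus + worst-case intra-pair spread
            if n_units == 1 or np.all(np.diff(starts) > min_gap + 46_000 + length):
                break
        else:
            raise RuntimeError(
                f"could not satisfy >50 kb spacing on {chrom}; "
                "use a larger genome (fewer loci per chromosome)"
            )
        for unit, start in zip(chrom_units, starts):
            start = int(start)
            first = GenomicLocus(unit[0], chrom, start, start + length - 1)
            loci.append(first)
            if len(unit) == 2:
                gap = int(rng.integers(1, 45_001))
                second_start = first.end + gap
                second = GenomicLocus(
                    unit[1], chrom, second_start, second_start + length - 1
                )
                loci.append(second)
                truth.cluster_pairs.append(
                    {
                        "mirnas": list(unit),
                        "chrom": chrom,
                        "gap": gap,
                        "rho": spec.cluster_rho,
                    }
                )
    for loc in loci:
        truth.loci.append(
            {
                "mirna": loc.mirna,
                "chrom": loc.chrom,
                "start": loc.start,
                "end": loc.end,
            }
        )
    return loci, truth
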