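"""Signed bipartite cancer-miRNA network: data model and I/O.

The network is a bipartite graph G = (U, V, E) with cancer types on one
side (U), miRNAs on the other (V), and an edge (u, v) whenever miRNA v is
reported dysregulated in cancer type u.  Each edge carries a sign: UP for
overexpression/amplification, DOWN for underexpression/deletion.  In the
Pajek rendering convention UP edges are drawn solid and DOWN edges dotted.

This module holds the in-memory containers plus readers/writers for the
tab-separated dysregulation edge list, miRNA genomic coordinates (BED and
GFF3), and Pajek ``.net``/``.clu`` export.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

__all__ = [
    "Direction",
    "DysregulationEdge",
    "SignedBipartiteNetwork",
    "TransactionDatabase",
    "GenomicLocus",
    "NetworkFormatError",
    "ConflictError",
    "read_edge_list",
    "write_edge_list",
    "read_loci",
    "to_transactions",
    "write_pajek",
    "read_pajek",
]


class NetworkFormatError(ValueError):
    """Malformed input: bad direction token, bad coordinates, missing column."""


class ConflictError(ValueError):
    """Duplicate (cancer, miRNA) rows with contradictory directions."""


class Direction(enum.Enum):
    """Sign of a dysregulation edge."""

    UP = "up"
    DOWN = "down"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Case-insensitive direction synonyms.  "deleted"/"underexpressed" count as
#: downregulation, "amplified"/"overexpressed" as upregulation.
_DIRECTION_SYNONYMS = {
    "up": Direction.UP,
    "overexpressed": Direction.UP,
    "amplified": Direction.UP,
    "u": Direction.UP,
    "down": Direction.DOWN,
    "underexpressed": Direction.DOWN,
    "deleted": Direction.DOWN,
    "d": Direction.DOWN,
}


def parse_direction(token: str) -> Direction:
    """Map a free-text direction token to :class:`Direction`.

    Raises
    ------
    NetworkFormatError
        If the token is not a recognised synonym.
    """
    try:
        return _DIRECTION_SYNONYMS[token.strip().lower()]
    except KeyError:
        raise NetworkFormatError(f"unknown direction token {token!r}") from None


@dataclass(frozen=True)
class DysregulationEdge:
    """One reported (cancer type, miRNA, direction) relationship.

    ``evidence`` carries optional free-form metadata (PubMed id, technique,
    fold change, ...); it is stored verbatim and never interpreted.
    """

    cancer: str
    mirna: str
    direction: Direction
    evidence: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.cancer:
            raise ValueError("edge cancer label must be non-empty")
        if not self.mirna:
            raise ValueError("edge miRNA label must be non-empty")
        if not isinstance(self.direction, Direction):
            raise TypeError("direction must be a Direction enum value")


@dataclass(frozen=True)
class GenomicLocus:
    """A miRNA locus in 1-based inclusive coordinates (GFF3 convention)."""

    mirna: str
    chrom: str
    start: int
    end: int
    strand: str = "."  # "+", "-" or "." (unknown)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise NetworkFormatError(
                f"{self.mirna}: start must be >= 1 (1-based), got {self.start}"
            )
        if self.end < self.start:
            raise NetworkFormatError(
                f"{self.mirna}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SignedBipartiteNetwork:
    """Immutable signed bipartite graph of cancer types and miRNAs.

    Invariants enforced at construction:

    * at most one edge per (cancer, miRNA) pair,
    * every edge endpoint appears in the corresponding node set,
    * no label is both a cancer and a miRNA.

    Node sets are ordered (insertion order of first appearance, or as given),
    so exports are deterministic.
    """

    __slots__ = ("_cancers", "_mirnas", "_edges", "_adj_cancer", "_adj_mirna")

    def __init__(
        self,
        cancers: Iterable[str],
        mirnas: Iterable[str],
        edges: Iterable[DysregulationEdge],
    ) -> None:
        self._cancers: tuple[str, ...] = tuple(dict.fromkeys(cancers))
        self._mirnas: tuple[str, ...] = tuple(dict.fromkeys(mirnas))
        overlap = set(self._cancers) & set(self._mirnas)
        if overlap:
            raise ValueError(f"labels appear in both node sets: {sorted(overlap)}")
        cancer_set = set(self._cancers)
        mirna_set = set(self._mirnas)
        self._edges: dict[tuple[str, str], DysregulationEdge] = {}
        self._adj_cancer: dict[str, dict[str, Direction]] = {c: {} for c in self._cancers}
        self._adj_mirna: dict[str, dict[str, Direction]] = {m: {} for m in self._mirnas}
        for e in edges:
            if e.cancer not in cancer_set:
                raise ValueError(f"edge cancer {e.cancer!r} not in cancer node set")
            if e.mirna not in mirna_set:
                raise ValueError(f"edge miRNA {e.mirna!r} not in miRNA node set")
            key = (e.cancer, e.mirna)
            if key in self._edges:
                raise ValueError(f"duplicate edge for pair {key}")
            self._edges[key] = e
            self._adj_cancer[e.cancer][e.mirna] = e.direction
            self._adj_mirna[e.mirna][e.cancer] = e.direction

    @classmethod
    def from_edges(cls, edges: Iterable[DysregulationEdge]) -> "SignedBipartiteNetwork":
        """Build a network whose node sets are exactly the edge endpoints."""
        edges = list(edges)
        return cls(
            (e.cancer for e in edges), (e.mirna for e in edges), edges
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def cancers(self) -> tuple[str, ...]:
        return self._cancers

    @property
    def mirnas(self) -> tuple[str, ...]:
        return self._mirnas

    @property
    def edges(self) -> tuple[DysregulationEdge, ...]:
        return tuple(self._edges.values())

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, cancer: str, mirna: str) -> bool:
        return (cancer, mirna) in self._edges

    def direction(self, cancer: str, mirna: str) -> Direction:
        return self._edges[(cancer, mirna)].direction

    def mirnas_of(self, cancer: str) -> dict[str, Direction]:
        """miRNA -> direction map for one cancer type."""
        try:
            return dict(self._adj_cancer[cancer])
        except KeyError:
            raise KeyError(f"unknown cancer node {cancer!r}") from None

    def cancers_of(self, mirna: str) -> dict[str, Direction]:
        """cancer -> direction map for one miRNA."""
        try:
            return dict(self._adj_mirna[mirna])
        except KeyError:
            raise KeyError(f"unknown miRNA node {mirna!r}") from None

    def degree(self, node: str) -> int:
        """Number of incident edges of a cancer or miRNA node."""
        if node in self._adj_cancer:
            return len(self._adj_cancer[node])
        if node in self._adj_mirna:
            return len(self._adj_mirna[node])
        raise KeyError(f"unknown node {node!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedBipartiteNetwork):
            return NotImplemented
        return (
            set(self._cancers) == set(other._cancers)
            and set(self._mirnas) == set(other._mirnas)
            and {k: v.direction for k, v in self._edges.items()}
            == {k: v.direction for k, v in other._edges.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SignedBipartiteNetwork({len(self._cancers)} cancers, "
            f"{len(self._mirnas)} miRNAs, {len(self._edges)} edges)"
        )


@dataclass
class TransactionDatabase:
    """Per-cancer miRNA item sets feeding association-rule mining.

    One transaction per cancer type; the items are the miRNAs dysregulated
    in that cancer (optionally restricted by sign).
    """

    transactions: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def items(self) -> frozenset[str]:
        """Union of all item sets."""
        out: set[str] = set()
        for t in self.transactions.values():
            out |= t
        return frozenset(out)


# -- edge-list I/O ---------------------------------------------------------


def _normalize_label(label: str) -> str:
    # identifiers are matched verbatim after lower-casing + trimming; no
    # alias resolution against miRNA registries is attempted
    return label.strip().lower()


def read_edge_list(
    source: TextIO | str,
    conflict_policy: str = "error",
) -> SignedBipartiteNetwork:
    """Read a tab-separated dysregulation edge list.

    The stream must have a header naming at least ``cancer``, ``mirna`` and
    ``direction`` columns (any order, extra columns become edge evidence).
    ``#`` comment lines are ignored.  Direction tokens map case-insensitively
    through the up/overexpressed/amplified and down/underexpressed/deleted
    synonym groups.

    Parameters
    ----------
    source
        Open text stream, path, or the TSV content itself.
    conflict_policy
        How to resolve duplicate (cancer, miRNA) rows with contradictory
        directions: ``error`` (default) raises :class:`ConflictError`,
        ``first`` keeps the first row, ``majority`` keeps the more frequent
        direction (ties fall back to the first row's direction).
    """
    if conflict_policy not in {"error", "first", "majority"}:
        raise ValueError(f"unknown conflict_policy {conflict_policy!r}")
    close = False
    if isinstance(source, str):
        if "\t" in source or "\n" in source:
            stream: TextIO = io.StringIO(source)
        else:
            stream = open(source, "r", encoding="utf-8")
            close = True
    else:
        stream = source
    try:
        return _read_edge_list_stream(stream, conflict_policy)
    finally:
        if close:
            stream.close()


def _read_edge_list_stream(
    stream: TextIO, conflict_policy: str
) -> SignedBipartiteNetwork:
    header: list[str] | None = None
    col: dict[str, int] = {}
    # (cancer, mirna) -> list of (Direction, evidence, line_no)
    seen: dict[tuple[str, str], list[tuple[Direction, dict | None, int]]] = {}
    cancers: dict[str, None] = {}
    mirnas: dict[str, None] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            col = {name: i for i, name in enumerate(header)}
            missing = {"cancer", "mirna", "direction"} - set(col)
            if missing:
                raise NetworkFormatError(
                    f"edge list header missing required column(s): {sorted(missing)}"
                )
            continue
        try:
            cancer = _normalize_label(fields[col["cancer"]])
            mirna = _normalize_label(fields[col["mirna"]])
            direction_token = fields[col["direction"]]
        except IndexError:
            raise NetworkFormatError(
                f"line {line_no}: expected at least {len(col)} tab-separated fields"
            ) from None
        if not cancer or not mirna:
            raise NetworkFormatError(f"line {line_no}: empty cancer or miRNA label")
        try:
            direction = parse_direction(direction_token)
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"line {line_no}: {exc}") from None
        evidence = {
            name: fields[i]
            for name, i in col.items()
            if name not in {"cancer", "mirna", "direction"} and i < len(fields)
        } or None
        cancers.setdefault(cancer, None)
        mirnas.setdefault(mirna, None)
        seen.setdefault((cancer, mirna), []).append((direction, evidence, line_no))
    if header is None:
        raise NetworkFormatError("edge list is empty: no header found")

    edges: list[DysregulationEdge] = []
    for (cancer, mirna), records in seen.items():
        directions = {d for d, _, _ in records}
        if len(directions) == 1:
            d0, ev0, _ = records[0]
            edges.append(DysregulationEdge(cancer, mirna, d0, ev0))
            continue
        if conflict_policy == "error":
            lines = ", ".join(str(ln) for _, _, ln in records)
            raise ConflictError(
                f"conflicting directions for ({cancer}, {mirna}) on lines {lines}"
            )
        if conflict_policy == "first":
            d0, ev0, _ = records[0]
            edges.append(DysregulationEdge(cancer, mirna, d0, ev0))
        else:  # majority; ties keep the first row's direction
            n_up = sum(1 for d, _, _ in records if d is Direction.UP)
            n_down = len(records) - n_up
            if n_up > n_down:
                winner = Direction.UP
            elif n_down > n_up:
                winner = Direction.DOWN
            else:
                winner = records[0][0]
            ev = next(ev for d, ev, _ in records if d is winner)
            edges.append(DysregulationEdge(cancer, mirna, winner, ev))
    return SignedBipartiteNetwork(cancers, mirnas, edges)


def write_edge_list(network: SignedBipartiteNetwork, stream: TextIO) -> None:
    """Serialize a network back to the TSV edge-list schema."""
    stream.write("cancer\tmirna\tdirection\n")
    for e in network.edges:
        stream.write(f"{e.cancer}\t{e.mirna}\t{e.direction.value}\n")


# -- genomic coordinates ---------------------------------------------------

_GFF3_NAME_RE = re.compile(r"(?:^|;)\s*Name=([^;]+)", re.IGNORECASE)
_GFF3_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)", re.IGNORECASE)


def read_loci(source: TextIO | str, format: str = "BED") -> list[GenomicLocus]:
    """Read miRNA loci from BED (0-based half-open) or GFF3 (1-based inclusive).

    All loci are returned in the internal 1-based inclusive convention.  The
    miRNA name is taken from BED column 4 or the GFF3 ``Name`` attribute
    (falling back to ``ID``).
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown coordinate format {format!r}")
    close = False
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            stream: TextIO = io.StringIO(source)
        else:
            stream = open(source, "r", encoding="utf-8")
            close = True
    else:
        stream = source
    try:
        if fmt == "BED":
            return _read_bed(stream)
        return _read_gff3(stream)
    finally:
        if close:
            stream.close()


def _read_bed(stream: TextIO) -> list[GenomicLocus]:
    loci = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise NetworkFormatError(
                f"BED line {line_no}: need >= 4 columns (chrom, start, end, name)"
            )
        chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
        try:
            start0, end0 = int(start_s), int(end_s)
        except ValueError:
            raise NetworkFormatError(
                f"BED line {line_no}: non-integer coordinates"
            ) from None
        if end0 <= start0:
            raise NetworkFormatError(
                f"BED line {line_no}: end {end0} <= start {start0} (0-based half-open)"
            )
        strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
        try:
            loci.append(
                GenomicLocus(_normalize_label(name), chrom, start0 + 1, end0, strand)
            )
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"BED line {line_no}: {exc}") from None
    return loci


def _read_gff3(stream: TextIO) -> list[GenomicLocus]:
    loci = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise NetworkFormatError(f"GFF3 line {line_no}: need 9 columns")
        chrom, start_s, end_s, strand, attrs = (
            fields[0],
            fields[3],
            fields[4],
            fields[6],
            fields[8],
        )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise NetworkFormatError(
                f"GFF3 line {line_no}: non-integer coordinates"
            ) from None
        m = _GFF3_NAME_RE.search(attrs) or _GFF3_ID_RE.search(attrs)
        if m is None:
            raise NetworkFormatError(
                f"GFF3 line {line_no}: no Name or ID attribute"
            )
        if strand not in {"+", "-"}:
            strand = "."
        try:
            loci.append(
                GenomicLocus(_normalize_label(m.group(1)), chrom, start, end, strand)
            )
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"GFF3 line {line_no}: {exc}") from None
    return loci


def write_bed(loci: Sequence[GenomicLocus], stream: TextIO) -> None:
    """Write loci as 6-column BED (internal 1-based inclusive -> 0-based half-open)."""
    for loc in loci:
        stream.write(
            f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{loc.mirna}\t0\t{loc.strand if loc.strand in '+-' else '.'}\n"
        )


# -- transactions ----------------------------------------------------------


def to_transactions(
    network: SignedBipartiteNetwork, sign_mode: str = "any"
) -> TransactionDatabase:
    """Project the network onto per-cancer miRNA item sets.

    ``sign_mode`` restricts which edges contribute items: ``any`` (default,
    dysregulation regardless of sign), ``up`` or ``down``.  Every cancer node
    yields a transaction, including cancers whose filtered item set is empty.
    """
    if sign_mode not in {"any", "up", "down"}:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    want: Direction | None = None
    if sign_mode == "up":
        want = Direction.UP
    elif sign_mode == "down":
        want = Direction.DOWN
    transactions = {}
    for cancer in network.cancers:
        items = {
            m
            for m, d in network.mirnas_of(cancer).items()
            if want is None or d is want
        }
        transactions[cancer] = frozenset(items)
    return TransactionDatabase(transactions)


# -- Pajek export ----------------------------------------------------------

_PAJEK_UP_STYLE = "Solid"
_PAJEK_DOWN_STYLE = "Dots"


def write_pajek(
    network: SignedBipartiteNetwork,
    net_stream: TextIO,
    clu_stream: TextIO | None = None,
) -> None:
    """Export to Pajek ``.net`` text (plus optional ``.clu`` bipartition).

    Cancers are listed first, then miRNAs — this vertex order is the
    bipartition contract.  Each edge line carries a Pajek line-pattern
    parameter: ``p Solid`` for upregulation, ``p Dots`` for downregulation,
    matching the solid/dotted drawing convention.
    """
    n_vertices = len(network.cancers) + len(network.mirnas)
    index = {}
    net_stream.write(f"*Vertices {n_vertices}\n")
    for i, label in enumerate(network.cancers + network.mirnas, start=1):
        index[label] = i
        net_stream.write(f'{i} "{label}"\n')
    net_stream.write("*Edges\n")
    for e in network.edges:
        style = _PAJEK_UP_STYLE if e.direction is Direction.UP else _PAJEK_DOWN_STYLE
        net_stream.write(f"{index[e.cancer]} {index[e.mirna]} 1 p {style}\n")
    if clu_stream is not None:
        clu_stream.write(f"*Vertices {n_vertices}\n")
        for _ in network.cancers:
            clu_stream.write("1\n")
        for _ in network.mirnas:
            clu_stream.write("2\n")


def read_pajek(net_stream: TextIO, clu_stream: TextIO) -> SignedBipartiteNetwork:
    """Re-import a network written by :func:`write_pajek`.

    The ``.clu`` partition identifies which vertices are cancers (class 1)
    and which are miRNAs (class 2); edge signs are recovered from the line
    pattern parameter.
    """
    lines = [ln.strip() for ln in net_stream if ln.strip()]
    if not lines or not lines[0].lower().startswith("*vertices"):
        raise NetworkFormatError("Pajek file must start with *Vertices")
    n = int(lines[0].split()[1])
    labels: dict[int, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("*"):
        m = re.match(r"(\d+)\s+\"(.*)\"", lines[i])
        if m is None:
            raise NetworkFormatError(f"bad Pajek vertex line: {lines[i]!r}")
        labels[int(m.group(1))] = m.group(2)
        i += 1
    if len(labels) != n:
        raise NetworkFormatError(f"expected {n} vertices, found {len(labels)}")
    classes: list[int] = []
    for ln in clu_stream:
        ln = ln.strip()
        if not ln or ln.lower().startswith("*vertices"):
            continue
        classes.append(int(ln))
    if len(classes) != n:
        raise NetworkFormatError("partition length does not match vertex count")
    cancers = [labels[k] for k in sorted(labels) if classes[k - 1] == 1]
    mirnas = [labels[k] for k in sorted(labels) if classes[k - 1] == 2]
    edges = []
    if i < len(lines) and lines[i].lower().startswith("*edges"):
        for ln in lines[i + 1 :]:
            if ln.startswith("*"):
                break
            parts = ln.split()
            a, b = int(parts[0]), int(parts[1])
            direction = Direction.UP
            if "p" in parts:
                style = parts[parts.index("p") + 1]
                direction = (
                    Direction.DOWN if style == _PAJEK_DOWN_STYLE else Direction.UP
                )
            la, lb = labels[a], labels[b]
            if classes[a - 1] == 2:  # miRNA listed first; normalise
                la, lb = lb, la
            edges.append(DysregulationEdge(la, lb, direction))
    return SignedBipartiteNetwork(cancers, mirnas, edges)
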