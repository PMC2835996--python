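"""Data model and I/O: edge lists, coordinates, transactions, Pajek."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from cminet.network import (
    ConflictError,
    Direction,
    DysregulationEdge,
    GenomicLocus,
    NetworkFormatError,
    SignedBipartiteNetwork,
    read_edge_list,
    read_loci,
    read_pajek,
    to_transactions,
    write_edge_list,
    write_pajek,
)
from cminet.network import write_bed


def tsv(*rows: str) -> str:
    return "cancer\tmirna\tdirection\n" + "\n".join(rows) + "\n"


class TestReadEdgeList:
    def test_basic_two_rows(self):
        net = read_edge_list(tsv("brain\tmiR-21\tup", "brain\tlet-7a-2\tdown"))
        assert len(net.cancers) == 1
        assert len(net.mirnas) == 2
        assert net.n_edges == 2
        assert net.direction("brain", "mir-21") is Direction.UP
        assert net.direction("brain", "let-7a-2") is Direction.DOWN

    @pytest.mark.parametrize(
        "token,expected",
        [
            ("up", Direction.UP),
            ("Overexpressed", Direction.UP),
            ("AMPLIFIED", Direction.UP),
            ("down", Direction.DOWN),
            ("underexpressed", Direction.DOWN),
            ("Deleted", Direction.DOWN),
        ],
    )
    def test_direction_synonyms(self, token, expected):
        net = read_edge_list(tsv(f"colon\tmiR-1\t{token}"))
        assert net.direction("colon", "mir-1") is expected

    def test_synonym_duplicates_collapse(self):
        net = read_edge_list(
            tsv("colon\tmiR-21\tup", "colon\tmiR-21\toverexpressed")
        )
        assert net.n_edges == 1
        assert net.direction("colon", "mir-21") is Direction.UP

    def test_conflict_policy_error(self):
        with pytest.raises(ConflictError, match="colon.*mir-21"):
            read_edge_list(tsv("colon\tmiR-21\tup", "colon\tmiR-21\tdown"))

    def test_conflict_policy_first_and_majority(self):
        rows = tsv("colon\tm\tdown", "colon\tm\tup", "colon\tm\tup")
        assert (
            read_edge_list(rows, conflict_policy="first").direction("colon", "m")
            is Direction.DOWN
        )
        assert (
            read_edge_list(rows, conflict_policy="majority").direction("colon", "m")
            is Direction.UP
        )

    def test_majority_tie_keeps_first(self):
        rows = tsv("colon\tm\tdown", "colon\tm\tup")
        assert (
            read_edge_list(rows, conflict_policy="majority").direction("colon", "m")
            is Direction.DOWN
        )

    def test_unknown_direction_names_line(self):
        with pytest.raises(NetworkFormatError, match="line 3"):
            read_edge_list(tsv("colon\tm\tup", "colon\tn\tsideways"))

    def test_missing_column_is_schema_error(self):
        with pytest.raises(NetworkFormatError, match="direction"):
            read_edge_list("cancer\tmirna\ncolon\tmiR-21\n")

    def test_extra_columns_become_evidence(self):
        net = read_edge_list(
            "cancer\tmirna\tdirection\tpubmed\ncolon\tmiR-21\tup\t12345\n"
        )
        (edge,) = net.edges
        assert edge.evidence == {"pubmed": "12345"}

    def test_comments_and_blank_lines_ignored(self):
        net = read_edge_list(
            "# curated network\ncancer\tmirna\tdirection\n\ncolon\tm\tup\n"
        )
        assert net.n_edges == 1


class TestNetworkInvariants:
    def test_label_in_both_sides_rejected(self):
        with pytest.raises(ValueError, match="both node sets"):
            SignedBipartiteNetwork(
                ["x"], ["x"], []
            )

    def test_duplicate_pair_rejected(self):
        e = DysregulationEdge("c", "m", Direction.UP)
        f = DysregulationEdge("c", "m", Direction.DOWN)
        with pytest.raises(ValueError, match="duplicate"):
            SignedBipartiteNetwork(["c"], ["m"], [e, f])

    def test_degree_and_conservation(self, small_network):
        net = small_network
        assert net.degree("a") == 2
        assert net.degree("b") == 1
        assert net.degree("c1") == 2
        assert sum(net.degree(c) for c in net.cancers) == net.n_edges
        assert sum(net.degree(m) for m in net.mirnas) == net.n_edges

    def test_isolated_node_degree_zero(self):
        net = SignedBipartiteNetwork(["c"], ["m"], [])
        assert net.degree("m") == 0

    def test_unknown_node_lookup_error(self, small_network):
        with pytest.raises(KeyError):
            small_network.degree("nope")

    def test_degree_increments_on_both_endpoints(self, small_network):
        net = small_network
        more = SignedBipartiteNetwork(
            net.cancers,
            net.mirnas,
            list(net.edges) + [DysregulationEdge("c2", "b", Direction.DOWN)],
        )
        assert more.degree("c2") == net.degree("c2") + 1
        assert more.degree("b") == net.degree("b") + 1


class TestTransactions:
    def test_mode_any(self, small_network):
        db = to_transactions(small_network, "any")
        assert db.transactions == {"c1": {"a", "b"}, "c2": {"a"}}

    def test_mode_down_keeps_empty_transactions(self, small_network):
        db = to_transactions(small_network, "down")
        assert db.transactions == {"c1": {"b"}, "c2": frozenset()}
        assert db.n_transactions == 2

    def test_empty_network(self):
        db = to_transactions(SignedBipartiteNetwork([], [], []))
        assert db.n_transactions == 0

    def test_itemset_sizes_equal_cancer_degrees(self, small_network):
        db = to_transactions(small_network, "any")
        for c in small_network.cancers:
            assert len(db.transactions[c]) == small_network.degree(c)


class TestLoci:
    def test_bed_zero_based_conversion(self):
        (loc,) = read_loci("chr11\t100\t180\tmiR-100\n", format="BED")
        assert (loc.chrom, loc.start, loc.end) == ("chr11", 101, 180)

    def test_gff3_identity_convention(self):
        line = "chr11\tmirbase\tmiRNA\t101\t180\t.\t+\t.\tID=X;Name=miR-100\n"
        (loc,) = read_loci(line, format="GFF3")
        assert (loc.start, loc.end, loc.strand) == (101, 180, "+")
        assert loc.mirna == "mir-100"

    def test_bed_end_not_after_start_is_error(self):
        with pytest.raises(NetworkFormatError, match="line 1"):
            read_loci("chr1\t100\t100\tm\n", format="BED")

    def test_bed_round_trip_is_identity(self):
        text = "chr1\t100\t180\tmir-a\t0\t+\nchr2\t0\t80\tmir-b\t0\t.\n"
        loci = read_loci(text, format="BED")
        out = io.StringIO()
        write_bed(loci, out)
        assert read_loci(out.getvalue(), format="BED") == loci

    def test_locus_invariants(self):
        with pytest.raises(NetworkFormatError):
            GenomicLocus("m", "chr1", 0, 10)
        with pytest.raises(NetworkFormatError):
            GenomicLocus("m", "chr1", 10, 5)


# TSV round-trip property over generated networks
@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    edges=st.lists(
        st.tuples(
            st.sampled_from(["c1", "c2", "c3"]),
            st.sampled_from(["m1", "m2", "m3", "m4"]),
            st.sampled_from([Direction.UP, Direction.DOWN]),
        ),
        unique_by=lambda e: (e[0], e[1]),
        max_size=12,
    )
)
def test_edge_list_round_trip(edges):
    net = SignedBipartiteNetwork.from_edges(
        [DysregulationEdge(c, m, d) for c, m, d in edges]
    )
    buf = io.StringIO()
    write_edge_list(net, buf)
    buf.seek(0)
    assert read_edge_list(buf) == net


class TestPajek:
    def test_vertex_and_edge_counts(self, small_network):
        more = SignedBipartiteNetwork(
            ["c1", "c2"],
            ["a", "b", "c"],
            list(small_network.edges)
            + [DysregulationEdge("c2", "c", Direction.DOWN)],
        )
        net_buf, clu_buf = io.StringIO(), io.StringIO()
        write_pajek(more, net_buf, clu_buf)
        text = net_buf.getvalue()
        assert text.startswith("*Vertices 5\n")
        assert sum(1 for ln in text.splitlines() if " p " in ln) == 4
        # bipartition: 2 cancers then 3 miRNAs
        classes = [ln for ln in clu_buf.getvalue().splitlines()[1:]]
        assert classes == ["1", "1", "2", "2", "2"]

    def test_empty_network(self):
        buf = io.StringIO()
        write_pajek(SignedBipartiteNetwork([], [], []), buf)
        assert buf.getvalue() == "*Vertices 0\n*Edges\n"

    def test_round_trip_recovers_edges_and_signs(self, small_network):
        net_buf, clu_buf = io.StringIO(), io.StringIO()
        write_pajek(small_network, net_buf, clu_buf)
        net_buf.seek(0)
        clu_buf.seek(0)
        assert read_pajek(net_buf, clu_buf) == small_network
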