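"""Tissue bias, exact-test oracle equivalence, hubs and specific miRNAs."""

import numpy as np
import pytest
from scipy import stats

from cminet.enrichment import (
    cancer_specific,
    direction_counts,
    fisher_bias_test,
    find_hubs,
    majority_direction_percentage,
    tissue_bias_table,
)
from cminet.network import Direction, DysregulationEdge, SignedBipartiteNetwork

import _oracles


def network_from_counts(counts: dict[str, tuple[int, int]]) -> SignedBipartiteNetwork:
    """Build a network with the given per-cancer (n_up, n_down) counts."""
    edges = []
    mirnas = []
    k = 0
    for cancer, (n_up, n_down) in counts.items():
        for _ in range(n_up):
            mirnas.append(f"m{k}")
            edges.append(DysregulationEdge(cancer, f"m{k}", Direction.UP))
            k += 1
        for _ in range(n_down):
            mirnas.append(f"m{k}")
            edges.append(DysregulationEdge(cancer, f"m{k}", Direction.DOWN))
            k += 1
    return SignedBipartiteNetwork(list(counts), mirnas, edges)


class TestDirectionCounts:
    def test_brain_like_fixture(self):
        net = network_from_counts({"brain": (5, 79), "other": (3, 3)})
        assert direction_counts(net, "brain") == (5, 79)

    def test_no_edges(self):
        net = SignedBipartiteNetwork(["c"], ["m"], [])
        assert direction_counts(net, "c") == (0, 0)

    def test_counts_sum_to_degree(self):
        net = network_from_counts({"a": (4, 7), "b": (2, 0)})
        for c in net.cancers:
            assert sum(direction_counts(net, c)) == net.degree(c)

    def test_unknown_cancer(self):
        net = network_from_counts({"a": (1, 0), "b": (0, 1)})
        with pytest.raises(KeyError):
            direction_counts(net, "nope")


class TestMajorityPercentage:
    @pytest.mark.parametrize(
        "n_up,n_down,direction,percent",
        [
            (5, 79, "Downregulated", 94.04),
            (0, 32, "Downregulated", 100.0),
            (4, 0, "Upregulated", 100.0),
            (9, 0, "Upregulated", 100.0),
            (15, 3, "Upregulated", 83.33),
            (42, 4, "Upregulated", 91.30),
            (10, 1, "Upregulated", 90.90),
            (9, 2, "Upregulated", 81.81),
        ],
    )
    def test_reported_tissue_percentages(self, n_up, n_down, direction, percent):
        """The eight published per-tissue majority percentages, recomputed."""
        assert majority_direction_percentage(n_up, n_down) == (direction, percent)

    def test_truncation_not_rounding(self):
        # 10/11 = 90.909...% must print 90.90, never 90.91
        _, p = majority_direction_percentage(10, 1)
        assert p == 90.90

    def test_tie_is_mixed(self):
        assert majority_direction_percentage(3, 3) == ("Mixed", 50.0)

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            majority_direction_percentage(0, 0)


class TestFisherBias:
    def test_diagonal_table_exact_value(self):
        # table [[5,0],[0,5]]: two-sided p = 2/252 by exhaustive enumeration
        net = network_from_counts({"x": (5, 0), "y": (0, 5)})
        r = fisher_bias_test(net, "x")
        assert r.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert (r.bg_up, r.bg_down) == (0, 5)

    def test_no_association_p_one(self):
        net = network_from_counts({"x": (2, 2), "y": (8, 8)})
        assert fisher_bias_test(net, "x").p_value == pytest.approx(1.0)

    def test_background_aggregates_all_other_cancers(self):
        net = network_from_counts({"x": (1, 2), "y": (3, 4), "z": (5, 6)})
        r = fisher_bias_test(net, "x")
        assert (r.n_up, r.n_down, r.bg_up, r.bg_down) == (1, 2, 8, 10)
        # conservation: experimental + background = all edges
        assert r.n_up + r.n_down + r.bg_up + r.bg_down == net.n_edges

    def test_requires_two_cancers(self):
        net = network_from_counts({"x": (1, 1)})
        with pytest.raises(ValueError):
            fisher_bias_test(net, "x")

    def test_column_swap_symmetry(self):
        net = network_from_counts({"x": (3, 7), "y": (11, 5)})
        swapped = network_from_counts({"x": (7, 3), "y": (5, 11)})
        assert fisher_bias_test(net, "x").p_value == pytest.approx(
            fisher_bias_test(swapped, "x").p_value
        )

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_oracle_equivalence_random_tables(self, sidedness):
        """Exact-test p equals exhaustive hypergeometric enumeration, 1000 tables."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            net = network_from_counts({"x": (int(a), int(b)), "y": (int(c), int(d))})
            p = fisher_bias_test(net, "x", sidedness).p_value
            if sidedness == "two-sided":
                expected = _oracles.fisher_two_sided(int(a), int(b), int(c), int(d))
            else:
                expected = _oracles.fisher_one_sided(
                    int(a), int(b), int(c), int(d), sidedness
                )
            assert p == pytest.approx(expected, abs=1e-9)

    def test_null_calibration_unbiased_signs(self):
        """With sign bias 0.5 everywhere, ~5% of cancers reach p <= 0.05."""
        rng = np.random.default_rng(7)
        n_cancers, per_cancer, reps = 20, 30, 25
        hits = total = 0
        for _ in range(reps):
            counts = {}
            for i in range(n_cancers):
                n_up = int(rng.binomial(per_cancer, 0.5))
                counts[f"c{i}"] = (n_up, per_cancer - n_up)
            net = network_from_counts(counts)
            for c in net.cancers:
                total += 1
                if fisher_bias_test(net, c).p_value <= 0.05:
                    hits += 1
        rate = hits / total
        se = (0.05 * 0.95 / total) ** 0.5
        assert rate <= 0.05 + 3 * se


class TestHubsAndSpecific:
    def _net(self):
        edges = []
        cancers = [f"c{i}" for i in range(8)]
        # hub-up: 5 cancers all UP; hub-het: 6 cancers 5 UP 1 DOWN;
        # near: 4 cancers; spec1: 1 cancer; spec3: 3 cancers
        for i in range(5):
            edges.append(DysregulationEdge(f"c{i}", "hub-up", Direction.UP))
        for i in range(5):
            edges.append(DysregulationEdge(f"c{i}", "hub-het", Direction.UP))
        edges.append(DysregulationEdge("c5", "hub-het", Direction.DOWN))
        for i in range(4):
            edges.append(DysregulationEdge(f"c{i}", "near", Direction.DOWN))
        edges.append(DysregulationEdge("c0", "spec1", Direction.DOWN))
        for i in range(3):
            edges.append(DysregulationEdge(f"c{i}", "spec3", Direction.UP))
        return SignedBipartiteNetwork(
            cancers, ["hub-up", "hub-het", "near", "spec1", "spec3"], edges
        )

    def test_hub_threshold_and_homogeneity(self):
        hubs = {h.mirna: h for h in find_hubs(self._net(), 5)}
        assert set(hubs) == {"hub-up", "hub-het"}
        assert hubs["hub-up"].homogeneity == "oncogenic-like"
        assert hubs["hub-het"].homogeneity == "heterogeneous"
        assert hubs["hub-het"].degree == 6
        # all-DOWN hub is suppressor-like
        edges = [
            DysregulationEdge(f"c{i}", "supp", Direction.DOWN) for i in range(5)
        ]
        net = SignedBipartiteNetwork([f"c{i}" for i in range(5)], ["supp"], edges)
        assert find_hubs(net, 5)[0].homogeneity == "suppressor-like"

    def test_sorted_by_degree_then_label(self):
        hubs = find_hubs(self._net(), 5)
        assert [h.mirna for h in hubs] == ["hub-het", "hub-up"]

    def test_min_degree_validation(self):
        with pytest.raises(ValueError):
            find_hubs(self._net(), 0)

    def test_cancer_specific_boundary(self):
        specific = {m for m, _, _ in cancer_specific(self._net(), 2)}
        assert specific == {"spec1"}
        specific3 = {m for m, _, _ in cancer_specific(self._net(), 3)}
        assert specific3 == {"spec1", "spec3"}

    def test_hub_and_specific_sets_disjoint(self):
        net = self._net()
        hubs = {h.mirna for h in find_hubs(net, 5)}
        specific = {m for m, _, _ in cancer_specific(net, 2)}
        assert hubs.isdisjoint(specific)


def test_tissue_bias_table_layout():
    net = network_from_counts({"a": (9, 2), "b": (1, 10), "c": (3, 3)})
    frame = tissue_bias_table(net)
    assert list(frame["cancer"]) == ["a", "b", "c"]
    row = frame.set_index("cancer").loc["a"]
    assert row["percent_majority"] == 81.81
    assert row["pattern"] == "Upregulated"
    assert 0 <= row["p_value"] <= 1
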