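"""Tissue-level dysregulation bias, hub miRNAs, and cancer-specific miRNAs.

For each cancer type the miRNAs dysregulated in it split into an up count
and a down count; the majority direction and its percentage (truncated to
two decimals) describe the tissue's dysregulation bias.  Whether that bias
exceeds what the rest of the network shows is assessed with Fisher's exact
test on the 2x2 table

    [[n_up, n_down],          # the cancer under test
     [bg_up, bg_down]]        # all edges of all OTHER cancers

Hubs are miRNAs dysregulated in >= 5 cancer types; miRNAs seen in <= 2
cancer types are reported as candidate tissue-specific miRNAs.  Hub
significance under the randomization null lives in :mod:`cminet.nulls`;
this module is purely descriptive counting plus the exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .network import Direction, SignedBipartiteNetwork

__all__ = [
    "TissueBiasResult",
    "HubReport",
    "direction_counts",
    "majority_direction_percentage",
    "fisher_bias_test",
    "tissue_bias_table",
    "find_hubs",
    "cancer_specific",
]


@dataclass(frozen=True)
class TissueBiasResult:
    cancer: str
    n_up: int
    n_down: int
    majority_direction: str  # "Upregulated" | "Downregulated" | "Mixed"
    majority_percent: float  # 0-100, truncated to 2 decimals
    bg_up: int
    bg_down: int
    odds_ratio: float
    odds_ratio_kind: str  # "conditional MLE" (flagged so sample OR is never confused)
    p_value: float


@dataclass(frozen=True)
class HubReport:
    mirna: str
    degree: int
    n_up: int
    n_down: int
    homogeneity: str  # "oncogenic-like" | "suppressor-like" | "heterogeneous"


def direction_counts(
    network: SignedBipartiteNetwork, cancer: str
) -> tuple[int, int]:
    """(n_up, n_down) over the edges incident to one cancer node."""
    directions = network.mirnas_of(cancer).values()
    n_up = sum(1 for d in directions if d is Direction.UP)
    return n_up, len(directions) - n_up


def majority_direction_percentage(n_up: int, n_down: int) -> tuple[str, float]:
    """Majority direction and its percentage, truncated to two decimals.

    Truncation (not rounding) matches the reporting convention in which
    10/11 prints as 90.90 and 9/11 as 81.81.  Equal counts yield
    ``("Mixed", 50.0)``.
    """
    total = n_up + n_down
    if total == 0:
        raise ValueError("percentage undefined: no edges")
    if n_up == n_down:
        return "Mixed", 50.0
    label = "Upregulated" if n_up > n_down else "Downregulated"
    # exact integer truncation to 2 decimals; no float rounding artefacts
    percent = (100 * max(n_up, n_down) * 100) // total / 100
    return label, percent


def fisher_bias_test(
    network: SignedBipartiteNetwork,
    cancer: str,
    sidedness: str = "two-sided",
) -> TissueBiasResult:
    """Exact test of one cancer's up/down split against the rest of the network.

    The experimental row is the cancer's own (n_up, n_down); the background
    row aggregates the up/down edges of every other cancer type.  The
    two-sided p-value follows the point-probability rule (sum of all
    hypergeometric tables no more probable than the observed one).
    """
    if sidedness not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if len(network.cancers) < 2:
        raise ValueError("background requires at least 2 cancer types")
    n_up, n_down = direction_counts(network, cancer)
    bg_up = bg_down = 0
    for other in network.cancers:
        if other == cancer:
            continue
        u, d = direction_counts(network, other)
        bg_up += u
        bg_down += d
    table = [[n_up, n_down], [bg_up, bg_down]]
    if n_up + n_down + bg_up + bg_down == 0:
        raise ValueError("exact test undefined: all four cells are zero")
    _, p = stats.fisher_exact(table, alternative=sidedness)
    try:
        orr = _odds_ratio(table, kind="conditional").statistic
    except ValueError:  # degenerate margins
        orr = float("nan")
    if n_up == n_down:
        direction, percent = "Mixed", 50.0
    else:
        direction, percent = majority_direction_percentage(n_up, n_down)
    return TissueBiasResult(
        cancer=cancer,
        n_up=n_up,
        n_down=n_down,
        majority_direction=direction,
        majority_percent=percent,
        bg_up=bg_up,
        bg_down=bg_down,
        odds_ratio=float(orr),
        odds_ratio_kind="conditional MLE",
        p_value=float(min(p, 1.0)),
    )


def tissue_bias_table(
    network: SignedBipartiteNetwork, sidedness: str = "two-sided"
) -> pd.DataFrame:
    """Per-cancer bias report mirroring the (cancer, %, pattern, p) layout."""
    rows = []
    for cancer in network.cancers:
        n_up, n_down = direction_counts(network, cancer)
        if n_up + n_down == 0:
            continue
        r = fisher_bias_test(network, cancer, sidedness)
        rows.append(
            {
                "cancer": r.cancer,
                "percent_majority": r.majority_percent,
                "pattern": r.majority_direction,
                "p_value": r.p_value,
                "n_up": r.n_up,
                "n_down": r.n_down,
                "bg_up": r.bg_up,
                "bg_down": r.bg_down,
                "odds_ratio": r.odds_ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer",
            "percent_majority",
            "pattern",
            "p_value",
            "n_up",
            "n_down",
            "bg_up",
            "bg_down",
            "odds_ratio",
        ],
    )


def find_hubs(
    network: SignedBipartiteNetwork, min_degree: int = 5
) -> list[HubReport]:
    """miRNAs dysregulated in >= ``min_degree`` cancer types.

    Homogeneous hubs carry a character label: all-UP hubs look oncogenic
    (upregulated wherever seen), all-DOWN hubs look tumor-suppressor-like.
    Sorted by degree descending, then label.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    hubs = []
    for mirna in network.mirnas:
        directions = network.cancers_of(mirna).values()
        degree = len(directions)
        if degree < min_degree:
            continue
        n_up = sum(1 for d in directions if d is Direction.UP)
        n_down = degree - n_up
        if n_down == 0:
            homogeneity = "oncogenic-like"
        elif n_up == 0:
            homogeneity = "suppressor-like"
        else:
            homogeneity = "heterogeneous"
        hubs.append(HubReport(mirna, degree, n_up, n_down, homogeneity))
    hubs.sort(key=lambda h: (-h.degree, h.mirna))
    return hubs


def cancer_specific(
    network: SignedBipartiteNetwork, max_degree: int = 2
) -> list[tuple[str, int, dict[str, Direction]]]:
    """miRNAs associated with 1..``max_degree`` cancer types (tissue-specific candidates)."""
    out = []
    for mirna in network.mirnas:
        assoc = network.cancers_of(mirna)
        if 1 <= len(assoc) <= max_degree:
            out.append((mirna, len(assoc), assoc))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
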