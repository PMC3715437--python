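"""Disorder-content comparison of human-yeast ortholog pairs.

Pairs in which neither member is appreciably disordered (neither above
30% disorder content) carry no signal about disorder evolution and are
set aside; the remaining pairs are categorized by the signed
difference of disorder contents, with differences under 5 percentage
points counted as similar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from .metrics import DisorderSummary
from .records import OrthologPairRecord

DC_THRESHOLD = 0.30  # strictly-greater filter on max(dc_human, dc_yeast)
SIMILAR_DELTA_PP = 5.0  # percentage points

CATEGORIES = ("similar", "human_higher", "yeast_higher", "below_threshold")


@dataclass
class OrthologComparison:
    pair: OrthologPairRecord
    dc_human: float
    dc_yeast: float
    delta_pp: float  # dc_human - dc_yeast, in percentage points
    category: str
    boundary_case: bool = False  # max dc exactly at the 30% threshold


def compare_orthologs(
    pairs: Sequence[OrthologPairRecord],
    summaries: Mapping[str, DisorderSummary],
) -> List[OrthologComparison]:
    """Categorize each ortholog pair by its disorder-content difference.

    ``below_threshold`` pairs (max disorder content <= 30%) are retained
    in the output but excluded from category tallies by
    :func:`category_tallies`.
    """
    out: List[OrthologComparison] = []
    for pair in pairs:
        for acc in (pair.human_accession, pair.yeast_accession):
            if acc not in summaries:
                raise ValueError(f"no disorder summary for accession {acc!r}")
        dc_h = summaries[pair.human_accession].disorder_content
        dc_y = summaries[pair.yeast_accession].disorder_content
        delta = (dc_h - dc_y) * 100.0
        if max(dc_h, dc_y) <= DC_THRESHOLD:
            category = "below_threshold"
        elif abs(delta) < SIMILAR_DELTA_PP:
            category = "similar"
        elif delta > 0:
            category = "human_higher"
        else:
            category = "yeast_higher"
        out.append(
            OrthologComparison(
                pair=pair,
                dc_human=dc_h,
                dc_yeast=dc_y,
                delta_pp=delta,
                category=category,
                boundary_case=max(dc_h, dc_y) == DC_THRESHOLD,
            )
        )
    return out


def category_tallies(comparisons: Sequence[OrthologComparison]) -> Dict[str, int]:
    """Counts per category over the above-threshold pairs."""
    tallies = {c: 0 for c in ("similar", "human_higher", "yeast_higher")}
    for comp in comparisons:
        if comp.category != "below_threshold":
            tallies[comp.category] += 1
    return tallies


ORTHOLOG_SCHEMA = [
    "human_accession", "yeast_accession", "dc_human", "dc_yeast", "delta_pp", "category",
]


def write_ortholog_report(comparisons: Sequence[OrthologComparison], path) -> None:
    from .io import write_table

    rows = [
        {
            "human_accession": c.pair.human_accession,
            "yeast_accession": c.pair.yeast_accession,
            "dc_human": c.dc_human,
            "dc_yeast": c.dc_yeast,
            "delta_pp": c.delta_pp,
            "category": c.category,
        }
        for c in comparisons
    ]
    write_table(rows, path, ORTHOLOG_SCHEMA, percent_columns=["dc_human", "dc_yeast"])
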