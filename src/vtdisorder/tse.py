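"""Structural analysis of tissue-specific exons (TSEs).

Exons whose inclusion level switches strongly across tissues (exon
switch score >= 0.25 by default) are mapped onto the protein chain,
their disorder content is read off the whole-protein prediction, and
predicted disordered binding regions (DBRs) overlapping the encoded
segment - or starting within a few residues of its boundaries - are
collected, since those are the interaction sites an exon switch can
add or remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .metrics import BinaryMask
from .records import FunctionalGroup, Segment, TSERecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_SWITCH = 0.25
DEFAULT_FLANK = 5


def select_tses(records: Sequence[TSERecord], min_switch: float = DEFAULT_MIN_SWITCH) -> List[TSERecord]:
    """Keep coding exons with switch score >= ``min_switch``."""
    kept: List[TSERecord] = []
    for rec in records:
        if not rec.coding:
            logger.info("excluding %s/%s: non-coding exon", rec.gene, rec.transcript_id)
            continue
        if rec.switch_score >= min_switch:
            kept.append(rec)
    return kept


def map_exon_to_protein(
    cds_exon_lengths: Sequence[int],
    tse_exon_index: int,
    rule: str = "majority",
) -> Optional[Segment]:
    """Map a CDS exon onto the residue span it encodes.

    Under the default codon-majority rule a residue (codon bases
    3r-2..3r in CDS coordinates) belongs to the exon when at least 2 of
    its 3 bases fall inside it; ``rule="first_base"`` assigns a residue
    to the exon containing its first codon base.  A trailing partial
    codon is ignored with a warning; an exon contributing no residues
    yields ``None``.
    """
    lengths = [int(x) for x in cds_exon_lengths]
    if not (1 <= tse_exon_index <= len(lengths)):
        raise ValueError(f"exon index {tse_exon_index} out of range for {len(lengths)} exons")
    total = sum(lengths)
    if total % 3 != 0:
        logger.warning("CDS length %d not divisible by 3; trailing partial codon ignored", total)
    n_residues = total // 3
    exon_start = sum(lengths[: tse_exon_index - 1]) + 1  # 1-based CDS coordinates
    exon_end = exon_start + lengths[tse_exon_index - 1] - 1

    first: Optional[int] = None
    last: Optional[int] = None
    for r in range(1, n_residues + 1):
        codon_start, codon_end = 3 * r - 2, 3 * r
        if rule == "majority":
            overlap = min(codon_end, exon_end) - max(codon_start, exon_start) + 1
            inside = overlap >= 2
        elif rule == "first_base":
            inside = exon_start <= codon_start <= exon_end
        else:
            raise ValueError(f"unknown mapping rule {rule!r}")
        if inside:
            if first is None:
                first = r
            last = r
    if first is None:
        logger.warning("exon %d contributes no residues under the %s rule", tse_exon_index, rule)
        return None
    return Segment(first, last)


def tse_disorder(span: Segment, mask: BinaryMask) -> Optional[float]:
    """Fraction of disordered residues within a protein span.

    TM-excluded residues inside the span leave both numerator and
    denominator; a span entirely inside a TM segment has no defined
    value and returns ``None``.
    """
    if span.end > len(mask):
        raise ValueError(f"span {span} outside protein of length {len(mask)}")
    sel = slice(span.start - 1, span.end)
    countable = ~mask.excluded[sel]
    total = int(countable.sum())
    if total == 0:
        return None
    return int((mask.flags[sel] & countable).sum()) / total


def tse_dbr_association(
    span: Segment, dbrs: Sequence[Segment], flank: int = DEFAULT_FLANK
) -> Tuple[List[Segment], List[Segment]]:
    """Split DBRs into span-overlapping and boundary-flanking sets.

    ``overlapping`` intersect the span itself; ``flank_only`` are
    disjoint from the span but touch its ``flank``-residue neighborhood
    on either side - binding regions most probably still affected by
    the presence or absence of the exon.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    overlapping: List[Segment] = []
    flank_only: List[Segment] = []
    for dbr in dbrs:
        if dbr.overlaps(span):
            overlapping.append(dbr)
            continue
        near = False
        if flank > 0:
            if span.start > 1:
                lo = max(1, span.start - flank)
                near = near or (dbr.start <= span.start - 1 and dbr.end >= lo)
            hi = span.end + flank
            near = near or (dbr.start <= hi and dbr.end >= span.end + 1)
        if near:
            flank_only.append(dbr)
    return overlapping, flank_only


@dataclass
class TSEStructureRow:
    """Structural annotation of one tissue-specific exon."""

    gene: str
    transcript_id: str
    switch_score: float
    routes: frozenset
    functional_group: FunctionalGroup
    protein_span: Segment
    tse_disorder_fraction: Optional[float]
    n_span_residues: int  # countable (non-TM) residues in the span
    n_disordered: int
    overlapping_dbrs: List[Segment] = field(default_factory=list)
    flank_dbrs: List[Segment] = field(default_factory=list)


def analyze_tse(
    record: TSERecord,
    mask: BinaryMask,
    dbrs: Sequence[Segment] = (),
    flank: int = DEFAULT_FLANK,
    mapping_rule: str = "majority",
) -> Optional[TSEStructureRow]:
    """Resolve a TSE record to its structural row (``None`` if it maps nowhere)."""
    if record.protein_span is not None:
        span = record.protein_span
    else:
        span = map_exon_to_protein(record.cds_exon_lengths, record.tse_exon_index, mapping_rule)
        if span is None:
            return None
    sel = slice(span.start - 1, span.end)
    countable = ~mask.excluded[sel]
    overlapping, flanking = tse_dbr_association(span, dbrs, flank)
    return TSEStructureRow(
        gene=record.gene,
        transcript_id=record.transcript_id,
        switch_score=record.switch_score,
        routes=record.routes,
        functional_group=record.functional_group,
        protein_span=span,
        tse_disorder_fraction=tse_disorder(span, mask),
        n_span_residues=int(countable.sum()),
        n_disordered=int((mask.flags[sel] & countable).sum()),
        overlapping_dbrs=list(overlapping),
        flank_dbrs=list(flanking),
    )


@dataclass
class TSEReport:
    n_tses: int
    total_residues: int
    total_disordered: int
    pooled_disorder_fraction: float
    per_route_counts: Dict[str, int]
    n_overlapping_dbrs: int
    n_flank_dbrs: int
    rows_more_disordered: List[bool]  # per row, vs the proteome reference


def tse_report(rows: Sequence[TSEStructureRow], proteome_disorder_reference: float) -> TSEReport:
    """Pool TSE rows into the route-level summary.

    The pooled disorder fraction is residue-weighted (total disordered
    TSE residues over total TSE residues); per-route counts list a
    multi-route exon once per route; each row is flagged when its own
    fraction exceeds the whole-proteome reference disorder content.
    """
    if not rows:
        raise ValueError("no TSE rows to report")
    total = sum(r.n_span_residues for r in rows)
    disordered = sum(r.n_disordered for r in rows)
    per_route: Dict[str, int] = {}
    for r in rows:
        for route in sorted(x.value for x in r.routes):
            per_route[route] = per_route.get(route, 0) + 1
    flags = [
        r.tse_disorder_fraction is not None
        and r.tse_disorder_fraction > proteome_disorder_reference
        for r in rows
    ]
    return TSEReport(
        n_tses=len(rows),
        total_residues=total,
        total_disordered=disordered,
        pooled_disorder_fraction=disordered / total if total else 0.0,
        per_route_counts=per_route,
        n_overlapping_dbrs=sum(len(r.overlapping_dbrs) for r in rows),
        n_flank_dbrs=sum(len(r.flank_dbrs) for r in rows),
        rows_more_disordered=flags,
    )


TSE_ROW_SCHEMA = [
    "gene", "transcript_id", "switch_score", "routes", "functional_group",
    "protein_span", "tse_disorder_fraction", "more_disordered_than_reference",
    "overlapping_dbrs", "flank_dbrs",
]


def write_tse_rows(rows: Sequence[TSEStructureRow], path, reference: float) -> None:
    from .io import write_table

    table = []
    for r in rows:
        table.append(
            {
                "gene": r.gene,
                "transcript_id": r.transcript_id,
                "switch_score": r.switch_score,
                "routes": "/".join(sorted(x.value for x in r.routes)),
                "functional_group": r.functional_group.value,
                "protein_span": str(r.protein_span),
                "tse_disorder_fraction": r.tse_disorder_fraction,
                "more_disordered_than_reference": (
                    r.tse_disorder_fraction is not None
                    and r.tse_disorder_fraction > reference
                ),
                "overlapping_dbrs": ";".join(str(s) for s in r.overlapping_dbrs),
                "flank_dbrs": ";".join(str(s) for s in r.flank_dbrs),
            }
        )
    write_table(table, path, TSE_ROW_SCHEMA, percent_columns=["tse_disorder_fraction"])
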