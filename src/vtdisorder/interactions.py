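"""Off-pathway (moonlighting) interaction-partner filtering and reporting.

High-confidence interaction partners of the trafficking proteins are
filtered in two steps: (1) partners too similar in sequence to any
protein of the trafficking dataset are dropped (>70% identity by
default), and near-duplicate partners of the same source are collapsed
to one representative by greedy longest-first clustering; (2) partners
on an explicit exclusion list (manually curated trafficking-related
proteins, promiscuous GTPase-family members) are dropped.  What
survives is counted as off-pathway, per source and per route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .metrics import DisorderSummary
from .records import FunctionalGroup, InteractionRecord, ProteinRecord, Route

logger = logging.getLogger(__name__)

REMOVAL_REASONS = ("low_confidence", "identity_to_pathway", "cluster_duplicate", "exclusion_list")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity of an optimal global alignment over the shorter length.

    Scoring is match 1 / mismatch 0 / no gap penalty, so the optimal
    score equals the maximum number of identically aligned columns;
    dividing by the shorter sequence length gives the identity
    convention of greedy clustering tools.  Symmetric by construction.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matches = _ALIGNER.score(a, b)
    return float(matches) / min(len(a), len(b))


@dataclass
class Cluster:
    representative_id: str
    representative_sequence: str
    member_ids: List[str]


def greedy_cluster(sequences: Sequence[Tuple[str, str]], threshold: float) -> List[Cluster]:
    """Greedy longest-first identity clustering with one representative per cluster.

    Sequences are sorted longest first (ties broken by identifier);
    each sequence joins the first cluster whose representative it
    matches at >= ``threshold`` identity, else founds a new cluster.
    The representative is always the founding (longest) member.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    clusters: List[Cluster] = []
    for ident, seq in ordered:
        for cluster in clusters:
            if pairwise_identity(seq, cluster.representative_sequence) >= threshold:
                cluster.member_ids.append(ident)
                break
        else:
            clusters.append(Cluster(ident, seq, [ident]))
    return clusters


@dataclass
class FilteredPartnerSet:
    """Filtering outcome for one source protein: kept ids and removals with reasons."""

    source_accession: str
    kept_partners: List[str]
    removed: List[Tuple[str, str]]  # (partner id, reason)

    def __post_init__(self) -> None:
        overlap = set(self.kept_partners) & {pid for pid, _ in self.removed}
        if overlap:
            raise ValueError(f"partners both kept and removed: {sorted(overlap)}")

    @property
    def n_kept(self) -> int:
        return len(self.kept_partners)


def filter_offpathway(
    edges: Sequence[InteractionRecord],
    pathway_sequences: Sequence[Tuple[str, str]],
    exclusion_ids: Iterable[str] = (),
    confidence_min: float = 0.9,
    identity_max: float = 0.70,
) -> List[FilteredPartnerSet]:
    """Apply the off-pathway partner filter to interaction edges.

    Per source, in order: drop edges below ``confidence_min``; drop
    partners more than ``identity_max`` identical to any pathway
    protein; collapse clusters of mutually similar surviving partners
    (greedy clustering at ``identity_max``, longest representative
    kept); drop partners on the exclusion list.  Every removal carries
    its reason, and kept + removed partition the input partner set.
    """
    if not pathway_sequences:
        raise ValueError("pathway sequence set is empty")
    exclusion = set(exclusion_ids)

    by_source: Dict[str, List[InteractionRecord]] = {}
    for edge in edges:
        by_source.setdefault(edge.source_accession, []).append(edge)

    # cache partner-vs-pathway identity screens: partners recur across sources
    pathway_hit_cache: Dict[str, bool] = {}

    def hits_pathway(seq: str) -> bool:
        if seq not in pathway_hit_cache:
            pathway_hit_cache[seq] = any(
                pairwise_identity(seq, pseq) > identity_max for _, pseq in pathway_sequences
            )
        return pathway_hit_cache[seq]

    results: List[FilteredPartnerSet] = []
    for source in sorted(by_source):
        kept: List[str] = []
        removed: List[Tuple[str, str]] = []
        survivors: List[InteractionRecord] = []
        for edge in by_source[source]:
            if edge.confidence < confidence_min:
                removed.append((edge.partner_id, "low_confidence"))
            elif hits_pathway(edge.partner_sequence):
                removed.append((edge.partner_id, "identity_to_pathway"))
            else:
                survivors.append(edge)
        clusters = greedy_cluster([(e.partner_id, e.partner_sequence) for e in survivors],
                                  identity_max)
        representatives = {c.representative_id for c in clusters}
        for edge in survivors:
            if edge.partner_id not in representatives:
                removed.append((edge.partner_id, "cluster_duplicate"))
            elif edge.partner_id in exclusion:
                removed.append((edge.partner_id, "exclusion_list"))
            else:
                kept.append(edge.partner_id)
        results.append(FilteredPartnerSet(source, kept, removed))
    return results


@dataclass
class InteractionReportRow:
    accession: str
    gene_name: str
    route: str
    n_offpathway: int
    length: Optional[int] = None
    disorder_content: Optional[float] = None
    n_ldr_30: Optional[int] = None
    n_dbr: Optional[int] = None
    dbr_residue_ratio: Optional[float] = None
    functional_group: str = "NONE"

    def __post_init__(self) -> None:
        if self.n_offpathway < 0:
            raise ValueError("n_offpathway must be >= 0")


@dataclass
class RouteInteractionSummary:
    route: str
    n_proteins: int
    total_interactions: int
    unique_partners: int
    mean_per_protein: float
    median_per_protein: float


def interaction_report(
    filtered: Sequence[FilteredPartnerSet],
    summaries: Mapping[str, DisorderSummary],
    annotations: Mapping[str, ProteinRecord],
    min_partners: int = 5,
) -> Tuple[List[RouteInteractionSummary], List[InteractionReportRow]]:
    """Per-route off-pathway totals and the most-interactive protein table.

    Totals count (source, partner) edges; unique partner counts are
    reported alongside because several sources may share a partner.
    Route means/medians are taken over all annotated proteins of the
    route, including those with zero surviving partners.  Report rows
    are restricted to sources with at least ``min_partners`` kept
    partners, sorted by descending count then accession; a multi-route
    protein appears once per route in the per-route totals but once in
    the row table (with its routes joined by '/').
    """
    kept_by_source = {f.source_accession: f for f in filtered}
    for f in filtered:
        if f.source_accession not in annotations:
            raise ValueError(f"source {f.source_accession} has no annotation")

    route_totals: List[RouteInteractionSummary] = []
    for route in sorted({r for rec in annotations.values() for r in rec.routes},
                        key=lambda r: r.value):
        members = [rec for rec in annotations.values() if route in rec.routes]
        counts = [kept_by_source[m.accession].n_kept if m.accession in kept_by_source else 0
                  for m in members]
        partners: Set[str] = set()
        for m in members:
            if m.accession in kept_by_source:
                partners.update(kept_by_source[m.accession].kept_partners)
        route_totals.append(
            RouteInteractionSummary(
                route=route.value,
                n_proteins=len(members),
                total_interactions=int(sum(counts)),
                unique_partners=len(partners),
                mean_per_protein=float(np.mean(counts)) if counts else 0.0,
                median_per_protein=float(np.median(counts)) if counts else 0.0,
            )
        )

    rows: List[InteractionReportRow] = []
    for f in filtered:
        if f.n_kept < min_partners:
            continue
        rec = annotations[f.source_accession]
        summary = summaries.get(f.source_accession)
        rows.append(
            InteractionReportRow(
                accession=f.source_accession,
                gene_name=rec.name,
                route="/".join(sorted(r.value for r in rec.routes)),
                n_offpathway=f.n_kept,
                length=rec.length,
                disorder_content=summary.disorder_content if summary else None,
                n_ldr_30=summary.n_ldr.get(30) if summary else None,
                n_dbr=summary.n_dbr if summary else None,
                dbr_residue_ratio=summary.dbr_residue_ratio if summary else None,
                functional_group=rec.functional_group.value,
            )
        )
    rows.sort(key=lambda r: (-r.n_offpathway, r.accession))
    return route_totals, rows


REPORT_SCHEMA = [
    "gene_name", "accession", "route", "n_offpathway", "length",
    "disorder_content", "n_ldr_30", "n_dbr", "dbr_residue_ratio", "functional_group",
]


def write_interaction_report(rows: Sequence[InteractionReportRow], path) -> None:
    from .io import write_table

    write_table(rows, path, REPORT_SCHEMA,
                percent_columns=["disorder_content", "dbr_residue_ratio"])


def read_interaction_report(path) -> List[InteractionReportRow]:
    """Read a report-shaped TSV (percent columns on the 0-100 scale)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def opt_int(v: str) -> Optional[int]:
        return None if v in ("", "NA") else int(v)

    def opt_pct(v: str) -> Optional[float]:
        return None if v in ("", "NA") else float(v) / 100.0

    return [
        InteractionReportRow(
            accession=row.accession,
            gene_name=row.gene_name,
            route=row.route,
            n_offpathway=int(row.n_offpathway),
            length=opt_int(row.length),
            disorder_content=opt_pct(row.disorder_content),
            n_ldr_30=opt_int(row.n_ldr_30),
            n_dbr=opt_int(row.n_dbr),
            dbr_residue_ratio=opt_pct(row.dbr_residue_ratio),
            functional_group=row.functional_group,
        )
        for row in df.itertuples(index=False)
    ]


def total_interactions(rows: Iterable[InteractionReportRow]) -> int:
    return sum(r.n_offpathway for r in rows)


def select_rows(
    rows: Iterable[InteractionReportRow],
    route: Optional[str] = None,
    functional_group: Optional[str] = None,
    exclude_genes: Iterable[str] = (),
) -> List[InteractionReportRow]:
    """Subset report rows by route and functional group, excluding named genes."""
    excluded = set(exclude_genes)
    out = []
    for r in rows:
        if route is not None and route not in r.route.split("/"):
            continue
        if functional_group is not None and r.functional_group != functional_group:
            continue
        if r.gene_name in excluded:
            continue
        out.append(r)
    return out
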