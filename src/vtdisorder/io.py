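"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA sequences, plain-text per-residue score tracks (one line
per residue: index, amino acid, score), and TSV annotation/report tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .records import (
    VALID_RESIDUES,
    FunctionalGroup,
    InteractionRecord,
    OrthologPairRecord,
    ProteinRecord,
    Route,
    ScoreTrack,
    Segment,
    Species,
    TrackKind,
    TSERecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    """Read a FASTA file into an ordered list of (identifier, sequence).

    Identifiers are the first whitespace-delimited token of the header;
    sequences are uppercased with gap and whitespace characters stripped.
    Duplicate identifiers and non-amino-acid characters are rejected.
    """
    records: List[Tuple[str, str]] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if ident in seen:
            raise ValueError(f"duplicate FASTA identifier {ident!r}")
        seen.add(ident)
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        for i, c in enumerate(seq, start=1):
            if c not in VALID_RESIDUES:
                raise ValueError(f"{ident}: invalid residue {c!r} at position {i}")
        records.append((ident, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_score_track(
    path: PathLike,
    kind: Union[TrackKind, str],
    sequence: Optional[str] = None,
) -> ScoreTrack:
    """Read a per-residue score track in the plain-text predictor dialect.

    Comment lines start with '#'.  Data lines are whitespace-separated
    and either 3-column (index, amino acid, score) or 2-column (index,
    score); indices must be 1-based and consecutive.  When ``sequence``
    is given the track is validated against it.
    """
    scores: List[float] = []
    residues: List[str] = []
    have_residues: Optional[bool] = None
    expected = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 3:
                idx_s, aa, score_s = fields
                row_has_residue = True
            elif len(fields) == 2:
                idx_s, score_s = fields
                aa = ""
                row_has_residue = False
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
            if have_residues is None:
                have_residues = row_has_residue
            elif have_residues != row_has_residue:
                raise ValueError(f"{path}:{lineno}: mixed 2- and 3-column lines")
            idx = int(idx_s)
            if idx != expected:
                raise ValueError(
                    f"{path}:{lineno}: non-consecutive residue index {idx} (expected {expected})"
                )
            expected += 1
            score = float(score_s)
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            scores.append(score)
            if row_has_residue:
                residues.append(aa.upper())
    if not scores:
        raise ValueError(f"no score lines found in {path}")
    track = ScoreTrack(
        kind=TrackKind(kind),
        scores=scores,
        residues="".join(residues) if have_residues else None,
    )
    if sequence is not None:
        track.validate_against(sequence)
    return track


def write_score_track(track: ScoreTrack, path: PathLike, sequence: Optional[str] = None) -> None:
    """Write a track in the 3-column dialect (2-column when no residues known)."""
    residues = track.residues or sequence
    with open(path, "w") as fh:
        fh.write(f"# kind: {track.kind.value}\n")
        for i, score in enumerate(track.scores, start=1):
            if residues is not None:
                fh.write(f"{i} {residues[i - 1]} {score:.4f}\n")
            else:
                fh.write(f"{i} {score:.4f}\n")


def _parse_routes(token: str) -> frozenset:
    token = token.strip()
    if not token:
        return frozenset()
    return frozenset(Route(t.strip()) for t in token.split(";") if t.strip())


def _parse_segments(token: str, row: int) -> Tuple[Segment, ...]:
    token = token.strip()
    if not token:
        return ()
    try:
        return tuple(Segment.parse(t) for t in token.split(";") if t.strip())
    except ValueError as exc:
        raise ValueError(f"row {row}: {exc}") from exc


ANNOTATION_COLUMNS = ["accession", "name", "species", "functional_group", "routes", "tm_segments"]


def read_annotation_table(path: PathLike, fasta_path: PathLike) -> List[ProteinRecord]:
    """Read the protein annotation TSV and attach sequences from a FASTA.

    Expected columns: accession, name, species, functional_group,
    routes (';'-separated), tm_segments (';'-separated "start-end").
    """
    sequences = dict(read_fasta(fasta_path))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: List[ProteinRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        acc = row.accession.strip()
        if acc not in sequences:
            raise ValueError(f"row {i}: accession {acc!r} absent from FASTA")
        try:
            rec = ProteinRecord(
                accession=acc,
                name=row.name.strip(),
                species=Species(row.species.strip()),
                sequence=sequences[acc],
                functional_group=FunctionalGroup(row.functional_group.strip() or "NONE"),
                routes=_parse_routes(row.routes),
                tm_segments=_parse_segments(row.tm_segments, i),
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_annotation_table(records: Sequence[ProteinRecord], path: PathLike) -> None:
    rows = [
        {
            "accession": r.accession,
            "name": r.name,
            "species": r.species.value,
            "functional_group": r.functional_group.value,
            "routes": ";".join(sorted(x.value for x in r.routes)),
            "tm_segments": ";".join(str(s) for s in sorted(r.tm_segments)),
        }
        for r in records
    ]
    write_table(rows, path, ANNOTATION_COLUMNS)


def write_table(
    rows: Iterable,
    path: PathLike,
    schema: Sequence[str],
    percent_columns: Sequence[str] = (),
) -> None:
    """Write records to a TSV with a fixed column order.

    Floating-point cells are rendered with 2 decimals; columns named in
    ``percent_columns`` are multiplied by 100 first (fractions printed
    as percentages, 0.6008 -> "60.08").  Row order is preserved, so
    re-writing identical rows yields a byte-identical file.
    """
    percent = set(percent_columns)

    def cell(row, col):
        if dataclasses.is_dataclass(row):
            value = getattr(row, col)
        else:
            value = row[col]
        if value is None:
            return "NA"
        if isinstance(value, bool):
            return "yes" if value else "no"
        if isinstance(value, float):
            if col in percent:
                value *= 100.0
            return f"{value:.2f}"
        return str(value)

    path = Path(path)
    rows = list(rows)
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            fh.write("\t".join(cell(row, col) for col in schema) + "\n")


def read_edges_table(path: PathLike) -> List[InteractionRecord]:
    """Read interaction edges: TSV columns (source, partner_id, partner_seq, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["source", "partner_id", "partner_seq", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        InteractionRecord(
            source_accession=row.source.strip(),
            partner_id=row.partner_id.strip(),
            partner_sequence=row.partner_seq.strip().upper(),
            confidence=float(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]


def read_tse_table(path: PathLike) -> List[TSERecord]:
    """Read a tissue-specific-exon table.

    Columns: gene, transcript_id, switch_score, routes, functional_group,
    coding, and either protein_span ("start-end") or cds_exon_lengths
    (';'-separated) + tse_exon_index.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: List[TSERecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        span_token = getattr(row, "protein_span", "").strip()
        lengths_token = getattr(row, "cds_exon_lengths", "").strip()
        index_token = getattr(row, "tse_exon_index", "").strip()
        kwargs = dict(
            gene=row.gene.strip(),
            transcript_id=row.transcript_id.strip(),
            switch_score=float(row.switch_score),
            routes=_parse_routes(getattr(row, "routes", "")),
            functional_group=FunctionalGroup(getattr(row, "functional_group", "NONE").strip() or "NONE"),
            coding=getattr(row, "coding", "yes").strip().lower() not in {"no", "false", "0"},
        )
        if span_token:
            kwargs["protein_span"] = Segment.parse(span_token)
        if lengths_token:
            kwargs["cds_exon_lengths"] = tuple(int(x) for x in lengths_token.split(";") if x.strip())
            kwargs["tse_exon_index"] = int(index_token)
        try:
            records.append(TSERecord(**kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
    return records


def read_ortholog_pairs(path: PathLike) -> List[OrthologPairRecord]:
    """Read ortholog pairs: TSV columns (human_accession, yeast_accession)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["human_accession", "yeast_accession"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        OrthologPairRecord(row.human_accession.strip(), row.yeast_accession.strip())
        for row in df.itertuples(index=False)
    ]


def read_exclusion_ids(path: PathLike) -> set:
    """Read an exclusion-id list: one identifier per line, '#' comments."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    return ids
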