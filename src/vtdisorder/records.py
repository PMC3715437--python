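"""Domain types shared by the whole pipeline.

All sequence intervals are 1-based and inclusive on both ends ("230-446"
style, the convention of curated protein annotation tables).  Helpers that
need half-open coordinates convert internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# the 20 standard residues plus the ambiguity/selenocysteine codes that
# occur in curated sequence databases
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")


class Species(str, enum.Enum):
    HUMAN = "human"
    YEAST = "yeast"
    OTHER = "other"


class FunctionalGroup(str, enum.Enum):
    """Functional classification of vesicle trafficking proteins.

    COAT - vesicle coat subunits; ASP - adaptor and sorting proteins;
    EARP - enzymatic activity related proteins; UCP - unclassified
    (mostly cargo receptors); MSTC - multisubunit tethering complexes;
    OFRP - other fusion regulators; SNARE - membrane fusion engines;
    NTSR - neurotransmitter transport specific regulators (human only);
    NONE - not part of the curated set (e.g. interaction partners).
    """

    COAT = "COAT"
    ASP = "ASP"
    EARP = "EARP"
    UCP = "UCP"
    MSTC = "MSTC"
    OFRP = "OFRP"
    SNARE = "SNARE"
    NTSR = "NTSR"
    NONE = "NONE"


class Route(str, enum.Enum):
    """The three main vesicle trafficking routes."""

    CLTR = "CLTR"  # clathrin-mediated
    COPI = "COPI"
    COPII = "COPII"


class TrackKind(str, enum.Enum):
    DISORDER = "disorder"
    BINDING = "binding"


@dataclass(frozen=True, order=True)
class Segment:
    """A 1-based, inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment {self.start}-{self.end}: need 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Segment") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __str__(self) -> str:  # "230-446" style
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, token: str) -> "Segment":
        """Parse a "start-end" token (en-dash tolerated)."""
        parts = token.strip().replace("–", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed segment token {token!r}")
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed segment token {token!r}") from exc
        return cls(start, end)


def _check_segments_within(segments: Sequence[Segment], length: int, what: str) -> None:
    for seg in segments:
        if seg.end > length:
            raise ValueError(f"{what} segment {seg} outside protein of length {length}")


def check_non_overlapping(segments: Sequence[Segment], what: str = "segment") -> None:
    ordered = sorted(segments)
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.overlaps(cur):
            raise ValueError(f"overlapping {what}s: {prev} and {cur}")


@dataclass
class ProteinRecord:
    """One protein of the curated vesicle trafficking dataset."""

    accession: str
    name: str
    species: Species
    sequence: str
    functional_group: FunctionalGroup = FunctionalGroup.NONE
    routes: frozenset = field(default_factory=frozenset)  # frozenset[Route]
    tm_segments: tuple = ()  # tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in VALID_RESIDUES]
        if bad:
            pos, char = bad[0]
            raise ValueError(f"{self.accession}: invalid residue {char!r} at position {pos}")
        self.routes = frozenset(Route(r) for r in self.routes)
        self.tm_segments = tuple(self.tm_segments)
        _check_segments_within(self.tm_segments, len(self.sequence), "transmembrane")
        check_non_overlapping(self.tm_segments, "transmembrane segment")
        if self.functional_group is FunctionalGroup.NTSR and self.species is not Species.HUMAN:
            raise ValueError(f"{self.accession}: NTSR group is defined for human proteins only")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """Per-residue prediction scores in [0, 1], one value per residue.

    ``residues`` (when present in the source file) allows cross-validation
    against the owning protein sequence.
    """

    kind: TrackKind
    scores: np.ndarray
    residues: Optional[str] = None

    def __post_init__(self) -> None:
        self.kind = TrackKind(self.kind)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.scores.size and (self.scores.min() < 0.0 or self.scores.max() > 1.0):
            raise ValueError("scores must lie in [0, 1]")
        if self.residues is not None and len(self.residues) != self.scores.size:
            raise ValueError("residue annotation length does not match scores")

    def __len__(self) -> int:
        return int(self.scores.size)

    def validate_against(self, sequence: str) -> None:
        """Check track length and, when available, per-residue letters."""
        if len(self) != len(sequence):
            raise ValueError(
                f"track length {len(self)} does not match sequence length {len(sequence)}"
            )
        if self.residues is not None:
            for i, (a, b) in enumerate(zip(self.residues, sequence), start=1):
                if a != b and "X" not in (a, b):
                    raise ValueError(f"residue mismatch at position {i}: track {a!r} vs sequence {b!r}")


@dataclass(frozen=True)
class DomainHit:
    """A Pfam-style entity assignment on a protein."""

    name: str
    span: Segment
    entity_class: str = "domain"  # family | domain | motif | repeat

    def __post_init__(self) -> None:
        if self.entity_class not in {"family", "domain", "motif", "repeat"}:
            raise ValueError(f"unknown entity class {self.entity_class!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """A (source protein, partner) edge prior to filtering."""

    source_accession: str
    partner_id: str
    partner_sequence: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if not self.partner_sequence:
            raise ValueError(f"partner {self.partner_id}: empty sequence")


@dataclass
class TSERecord:
    """A tissue-specific exon bound to one transcript.

    Exactly one of (``cds_exon_lengths`` + ``tse_exon_index``) or
    ``protein_span`` must be given: the former triggers codon-level
    mapping, the latter consumes a pre-mapped protein interval directly.
    """

    gene: str
    transcript_id: str
    switch_score: float
    routes: frozenset = field(default_factory=frozenset)
    functional_group: FunctionalGroup = FunctionalGroup.NONE
    coding: bool = True
    cds_exon_lengths: Optional[tuple] = None
    tse_exon_index: Optional[int] = None
    protein_span: Optional[Segment] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.switch_score <= 1.0):
            raise ValueError(f"{self.gene}: switch score {self.switch_score} outside [0, 1]")
        self.routes = frozenset(Route(r) for r in self.routes)
        has_exon_mode = self.cds_exon_lengths is not None and self.tse_exon_index is not None
        has_span_mode = self.protein_span is not None
        if has_exon_mode == has_span_mode:
            raise ValueError(
                f"{self.gene}/{self.transcript_id}: exactly one of exon-structure "
                "or protein-span input is required"
            )
        if has_exon_mode:
            self.cds_exon_lengths = tuple(int(x) for x in self.cds_exon_lengths)
            if any(x < 1 for x in self.cds_exon_lengths):
                raise ValueError(f"{self.gene}: exon lengths must be positive")
            if not (1 <= self.tse_exon_index <= len(self.cds_exon_lengths)):
                raise ValueError(f"{self.gene}: exon index {self.tse_exon_index} out of range")


@dataclass(frozen=True)
class OrthologPairRecord:
    """A human-yeast ortholog pair (detection is upstream; pairs are consumed)."""

    human_accession: str
    yeast_accession: str
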