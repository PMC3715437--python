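"""Synthetic proteins, score tracks and cohorts with known ground truth.

Every pipeline stage can be exercised without external predictors or
downloads: proteins are planted with an explicit ordered / disordered /
transmembrane segment architecture (plus binding regions inside the
disordered stretches), score tracks are the ground-truth labels with
bounded truncated-Gaussian noise, and cohorts draw per-protein planted
disorder fractions around group target means so that between-group
effect sizes are controlled exactly.

A toy propensity predictor (sliding-window average of a per-residue
disorder propensity scale) is included as an explicit stand-in for
external disorder predictors; it is deliberately simple and is used
only to generate plausible, label-correlated tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io import write_annotation_table, write_score_track
from .records import (
    FunctionalGroup,
    ProteinRecord,
    Route,
    ScoreTrack,
    Segment,
    Species,
    TrackKind,
)

logger = logging.getLogger(__name__)

SEGMENT_LABELS = ("ordered", "disordered", "tm")

# Mean score emitted for residues of each ground-truth class, before noise.
DISORDERED_CENTER = 0.8
ORDERED_CENTER = 0.2

# TOP-IDP-style per-residue disorder propensity scale (order-promoting
# residues negative, disorder-promoting positive).
DISORDER_PROPENSITY = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": -0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "K": 0.586, "S": 0.341, "E": 0.736, "P": 0.987,
}

# residue pools biased by structural class, so the toy propensity
# predictor correlates with the planted labels
DISORDER_POOL = list("PESKQGRAD")
ORDER_POOL = list("WFIYVLCNMHT")
TM_POOL = list("LIVFAM")


@dataclass
class ArchitectureSpec:
    """Ground-truth segment layout of one synthetic protein."""

    segments: Sequence[Tuple[int, str]]  # (length, "ordered"|"disordered"|"tm")
    dbr_segments: Sequence[Segment] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for length, label in self.segments:
            if length < 1:
                raise ValueError("segment lengths must be >= 1")
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
        if sum(length for length, _ in self.segments) < 1:
            raise ValueError("architecture must contain at least one residue")


@dataclass
class GroupSpec:
    label: str
    n_proteins: int
    target_mean_dc: float
    dc_sd: float
    length_range: Tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not (0.0 <= self.target_mean_dc <= 1.0):
            raise ValueError("target_mean_dc must lie in [0, 1]")
        if self.dc_sd < 0:
            raise ValueError("dc_sd must be >= 0")


@dataclass
class CohortSpec:
    groups: Sequence[GroupSpec]
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def plant_architecture(spec: ArchitectureSpec):
    """Expand a segment layout into per-residue ground truth.

    Returns ``(disorder_labels, tm_segments, dbr_segments)`` where
    ``disorder_labels`` is a boolean vector (transmembrane residues are
    labelled ordered - a membrane-embedded stretch is not disordered).
    """
    labels: List[bool] = []
    tm_segments: List[Segment] = []
    pos = 1
    for length, label in spec.segments:
        if label == "tm":
            tm_segments.append(Segment(pos, pos + length - 1))
        labels.extend([label == "disordered"] * length)
        pos += length
    label_vec = np.array(labels, dtype=bool)
    for dbr in spec.dbr_segments:
        if dbr.end > label_vec.size or not label_vec[dbr.start - 1 : dbr.end].all():
            raise ValueError(f"DBR {dbr} outside the planted disordered regions")
    return label_vec, tm_segments, list(spec.dbr_segments)


def _truncated_scores(centers: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return centers.copy()
    a = (0.0 - centers) / noise_sd
    b = (1.0 - centers) / noise_sd
    return sps.truncnorm.rvs(a, b, loc=centers, scale=noise_sd, random_state=rng)


def synth_tracks(
    disorder_labels: np.ndarray,
    dbr_segments: Sequence[Segment] = (),
    noise_sd: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ScoreTrack, ScoreTrack]:
    """Score tracks from ground-truth labels plus bounded noise.

    Disordered residues score around 0.8, ordered around 0.2, with
    truncated-Gaussian noise of standard deviation ``noise_sd`` (scores
    stay in [0, 1]); the binding track is built the same way over the
    planted binding-region labels.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    disorder_labels = np.asarray(disorder_labels, dtype=bool)
    centers = np.where(disorder_labels, DISORDERED_CENTER, ORDERED_CENTER)
    disorder = ScoreTrack(TrackKind.DISORDER, _truncated_scores(centers, noise_sd, rng))
    dbr_labels = np.zeros(disorder_labels.size, dtype=bool)
    for seg in dbr_segments:
        dbr_labels[seg.start - 1 : seg.end] = True
    centers_b = np.where(dbr_labels, DISORDERED_CENTER, ORDERED_CENTER)
    binding = ScoreTrack(TrackKind.BINDING, _truncated_scores(centers_b, noise_sd, rng))
    return disorder, binding


def synth_sequence(
    disorder_labels: np.ndarray,
    tm_segments: Sequence[Segment] = (),
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Random sequence with composition biased by the planted labels."""
    if rng is None:
        rng = np.random.default_rng()
    tm = np.zeros(len(disorder_labels), dtype=bool)
    for seg in tm_segments:
        tm[seg.start - 1 : seg.end] = True
    out = []
    for i, disordered in enumerate(np.asarray(disorder_labels, dtype=bool)):
        pool = TM_POOL if tm[i] else (DISORDER_POOL if disordered else ORDER_POOL)
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def sample_planted_contents(group: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    """Planted per-protein disorder fractions for one group (truncated Gaussian)."""
    if group.dc_sd == 0:
        return np.full(group.n_proteins, group.target_mean_dc)
    a = (0.0 - group.target_mean_dc) / group.dc_sd
    b = (1.0 - group.target_mean_dc) / group.dc_sd
    return sps.truncnorm.rvs(a, b, loc=group.target_mean_dc, scale=group.dc_sd,
                             size=group.n_proteins, random_state=rng)


def random_architecture(
    length: int,
    disorder_fraction: float,
    rng: np.random.Generator,
    dbr_prob: float = 0.7,
) -> ArchitectureSpec:
    """A plausible segment layout realizing a planted disorder fraction.

    The disordered residues form 1-3 contiguous blocks (long blocks are
    split) placed between ordered stretches; binding regions of 6-30
    residues are planted inside disordered blocks with probability
    ``dbr_prob`` per block.
    """
    n_dis = int(round(length * disorder_fraction))
    n_dis = max(0, min(length, n_dis))
    if n_dis == 0:
        return ArchitectureSpec(segments=[(length, "ordered")])
    if n_dis == length:
        blocks = [n_dis]
        n_ord = 0
    else:
        n_blocks = 1 if n_dis < 60 else int(rng.integers(1, 4))
        n_blocks = min(n_blocks, n_dis)
        cuts = np.sort(rng.choice(np.arange(1, n_dis), size=n_blocks - 1, replace=False)) if n_blocks > 1 else np.array([], dtype=int)
        blocks = np.diff(np.concatenate([[0], cuts, [n_dis]])).tolist()
        n_ord = length - n_dis
    # distribute ordered residues into the n_blocks+1 gaps around blocks
    segments: List[Tuple[int, str]] = []
    n_gaps = len(blocks) + 1
    if n_ord:
        gap_sizes = rng.multinomial(n_ord, np.full(n_gaps, 1.0 / n_gaps))
    else:
        gap_sizes = np.zeros(n_gaps, dtype=int)
    pos = 1
    dbrs: List[Segment] = []
    for i, block in enumerate(blocks):
        if gap_sizes[i]:
            segments.append((int(gap_sizes[i]), "ordered"))
            pos += int(gap_sizes[i])
        segments.append((int(block), "disordered"))
        if block >= 6 and rng.random() < dbr_prob:
            dbr_len = int(rng.integers(6, min(block, 30) + 1))
            offset = int(rng.integers(0, block - dbr_len + 1))
            dbrs.append(Segment(pos + offset, pos + offset + dbr_len - 1))
        pos += int(block)
    if gap_sizes[-1]:
        segments.append((int(gap_sizes[-1]), "ordered"))
    return ArchitectureSpec(segments=segments, dbr_segments=dbrs)


@dataclass
class SyntheticCohort:
    """Paths and ground truth of one generated cohort."""

    fasta: Path
    disorder_dir: Path
    anchor_dir: Path
    annotations: Path
    planted_fractions: Dict[str, float]
    group_of: Dict[str, str]


def synth_cohort(spec: CohortSpec, out_dir) -> SyntheticCohort:
    """Generate a cohort on disk in exactly the formats the readers consume.

    Writes ``cohort.fasta``, per-protein disorder and binding tracks
    under ``tracks/disorder`` and ``tracks/anchor``, and
    ``annotations.tsv``.  Group labels are stored as route labels when
    they name one of the three trafficking routes, otherwise as plain
    functional-group-free annotations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    disorder_dir = out_dir / "tracks" / "disorder"
    anchor_dir = out_dir / "tracks" / "anchor"
    disorder_dir.mkdir(parents=True, exist_ok=True)
    anchor_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    route_names = {r.value for r in Route}
    records: List[ProteinRecord] = []
    planted: Dict[str, float] = {}
    group_of: Dict[str, str] = {}
    fasta_path = out_dir / "cohort.fasta"
    with open(fasta_path, "w") as fasta:
        for group in spec.groups:
            fractions = sample_planted_contents(group, rng)
            for i, fraction in enumerate(fractions, start=1):
                accession = f"SYN{group.label}{i:04d}"
                lo, hi = group.length_range
                length = int(rng.integers(lo, hi + 1))
                arch = random_architecture(length, float(fraction), rng)
                labels, tm_segments, dbrs = plant_architecture(arch)
                sequence = synth_sequence(labels, tm_segments, rng)
                disorder, binding = synth_tracks(labels, dbrs, spec.noise_sd, rng=rng)
                fasta.write(f">{accession} synthetic {group.label}\n{sequence}\n")
                write_score_track(disorder, disorder_dir / f"{accession}.txt", sequence)
                write_score_track(binding, anchor_dir / f"{accession}.txt", sequence)
                records.append(
                    ProteinRecord(
                        accession=accession,
                        name=accession,
                        species=Species.OTHER,
                        sequence=sequence,
                        functional_group=FunctionalGroup.NONE,
                        routes=frozenset({group.label} & route_names),
                        tm_segments=tuple(tm_segments),
                    )
                )
                planted[accession] = float(labels.mean())
                group_of[accession] = group.label
    annotations = out_dir / "annotations.tsv"
    write_annotation_table(records, annotations)
    return SyntheticCohort(
        fasta=fasta_path,
        disorder_dir=disorder_dir,
        anchor_dir=anchor_dir,
        annotations=annotations,
        planted_fractions=planted,
        group_of=group_of,
    )


def propensity_track(
    sequence: str,
    scale: Optional[Mapping[str, float]] = None,
    window: int = 21,
) -> ScoreTrack:
    """Toy disorder-propensity predictor: windowed scale average in [0, 1].

    The per-residue propensity scale is averaged over a centered
    sliding window (truncated at the termini) and min-max scaled to
    [0, 1] using the range of the scale itself.  This is a stand-in
    used to produce plausible score tracks, not a reimplementation of
    any energy-based predictor.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if scale is None:
        scale = DISORDER_PROPENSITY
    values = sorted(scale.values())
    median = values[len(values) // 2]
    lo, hi = min(values), max(values)
    raw = np.empty(len(sequence))
    for i, residue in enumerate(sequence):
        if residue not in scale:
            logger.warning("residue %r absent from propensity scale; using scale median", residue)
            raw[i] = median
        else:
            raw[i] = scale[residue]
    half = window // 2
    smoothed = np.empty_like(raw)
    cumsum = np.concatenate([[0.0], np.cumsum(raw)])
    n = raw.size
    for i in range(n):
        a = max(0, i - half)
        b = min(n, i + half + 1)
        smoothed[i] = (cumsum[b] - cumsum[a]) / (b - a)
    squashed = np.clip((smoothed - lo) / (hi - lo), 0.0, 1.0)
    return ScoreTrack(TrackKind.DISORDER, squashed)
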