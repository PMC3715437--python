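"""Per-protein intrinsic disorder metrics.

Three measures are computed from per-residue predictor tracks after
binarization at a score threshold (default 0.5, score >= threshold =
disordered/binding):

* disorder content - disordered residues / residues considered;
* LDR residue ratio - residues in maximal disordered runs of at least
  k consecutive residues (k = 30, 50, 100 by default), / residues
  considered;
* DBR residue ratio - same construction on the binding track, with a
  configurable minimum region length.

Residues inside annotated transmembrane segments are excluded from
every metric: they are removed from numerator and denominator alike,
and (by default) a run of disordered residues does not continue across
an excised transmembrane stretch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .records import ProteinRecord, ScoreTrack, Segment, check_non_overlapping

DEFAULT_K_VALUES = (30, 50, 100)
DEFAULT_DBR_MIN_LEN = 6


@dataclass
class BinaryMask:
    """Binary per-residue classification plus the excluded (TM) residues."""

    flags: np.ndarray  # bool, True = disordered (or binding)
    excluded: np.ndarray  # bool, True = transmembrane, removed from metrics

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.flags.shape != self.excluded.shape:
            raise ValueError("flags and excluded must have the same length")

    def __len__(self) -> int:
        return int(self.flags.size)

    @property
    def effective_length(self) -> int:
        """Number of residues considered (total minus excluded)."""
        return int((~self.excluded).sum())

    @property
    def countable_flags(self) -> np.ndarray:
        return self.flags & ~self.excluded

    @property
    def n_true(self) -> int:
        return int(self.countable_flags.sum())


@dataclass(frozen=True)
class Run:
    """A maximal stretch of countable positive residues, in protein coordinates."""

    span: Segment

    @property
    def length(self) -> int:
        return self.span.length


@dataclass
class DisorderSummary:
    """The per-protein disorder metrics.

    ``dbr_residue_ratio``/``n_dbr`` are ``None`` (not zero) when no
    binding track was available for the protein.
    """

    accession: str
    length: int
    effective_length: int
    disorder_content: float
    ldr_residue_ratio: Dict[int, float]
    n_ldr: Dict[int, int]
    dbr_residue_ratio: Optional[float] = None
    n_dbr: Optional[int] = None

    def has_ldr(self, k: int) -> bool:
        return self.n_ldr[k] > 0

    @property
    def k_values(self) -> Tuple[int, ...]:
        return tuple(sorted(self.ldr_residue_ratio))


def binarize_track(track: ScoreTrack, threshold: float = 0.5) -> np.ndarray:
    """Map a score track to booleans: score >= threshold counts as positive."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return np.asarray(track.scores) >= threshold


def apply_tm_mask(flags: Sequence[bool], tm_segments: Sequence[Segment]) -> BinaryMask:
    """Mark transmembrane residues as excluded from all metrics."""
    flags = np.asarray(flags, dtype=bool)
    check_non_overlapping(tm_segments, "transmembrane segment")
    excluded = np.zeros(flags.size, dtype=bool)
    for seg in tm_segments:
        if seg.end > flags.size:
            raise ValueError(f"transmembrane segment {seg} outside protein of length {flags.size}")
        excluded[seg.start - 1 : seg.end] = True
    return BinaryMask(flags=flags, excluded=excluded)


def find_runs(mask: BinaryMask, k: int, join_excluded: bool = False) -> List[Run]:
    """Maximal runs of countable positive residues with length >= k.

    With ``join_excluded=False`` (default) an excluded residue breaks a
    run; with ``join_excluded=True`` excluded residues are transparent:
    a run may span them but they never count toward its length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    runs: List[Run] = []
    start: Optional[int] = None  # 1-based start of current run
    count = 0
    last_positive = 0

    def flush() -> None:
        nonlocal start, count
        if start is not None and count >= k:
            runs.append(Run(Segment(start, last_positive)))
        start, count = None, 0

    for pos in range(1, len(mask) + 1):
        i = pos - 1
        if mask.excluded[i]:
            if not join_excluded:
                flush()
            continue
        if mask.flags[i]:
            if start is None:
                start = pos
            count += 1
            last_positive = pos
        else:
            flush()
    flush()
    return runs


def _ratio_from_runs(runs: Sequence[Run], effective_length: int) -> float:
    if effective_length == 0:
        return 0.0
    total = sum(r.length for r in runs)
    return total / effective_length


def summarize_protein(
    protein: ProteinRecord,
    disorder_track: ScoreTrack,
    binding_track: Optional[ScoreTrack] = None,
    k_values: Iterable[int] = DEFAULT_K_VALUES,
    dbr_min_len: int = DEFAULT_DBR_MIN_LEN,
    threshold: float = 0.5,
    join_excluded: bool = False,
) -> DisorderSummary:
    """Compute the per-protein disorder metrics from its score tracks."""
    disorder_track.validate_against(protein.sequence)
    mask = apply_tm_mask(binarize_track(disorder_track, threshold), protein.tm_segments)
    eff = mask.effective_length
    disorder_content = mask.n_true / eff if eff else 0.0

    ldr_ratio: Dict[int, float] = {}
    n_ldr: Dict[int, int] = {}
    for k in sorted(set(int(k) for k in k_values)):
        runs = find_runs(mask, k, join_excluded=join_excluded)
        ldr_ratio[k] = _ratio_from_runs(runs, eff)
        n_ldr[k] = len(runs)

    dbr_ratio: Optional[float] = None
    n_dbr: Optional[int] = None
    if binding_track is not None:
        binding_track.validate_against(protein.sequence)
        bmask = apply_tm_mask(binarize_track(binding_track, threshold), protein.tm_segments)
        bruns = find_runs(bmask, dbr_min_len, join_excluded=join_excluded)
        dbr_ratio = _ratio_from_runs(bruns, eff)
        n_dbr = len(bruns)

    return DisorderSummary(
        accession=protein.accession,
        length=protein.length,
        effective_length=eff,
        disorder_content=disorder_content,
        ldr_residue_ratio=ldr_ratio,
        n_ldr=n_ldr,
        dbr_residue_ratio=dbr_ratio,
        n_dbr=n_dbr,
    )


def dbr_regions(
    protein: ProteinRecord,
    binding_track: ScoreTrack,
    dbr_min_len: int = DEFAULT_DBR_MIN_LEN,
    threshold: float = 0.5,
) -> List[Segment]:
    """Predicted disordered binding regions as protein-coordinate segments."""
    binding_track.validate_against(protein.sequence)
    mask = apply_tm_mask(binarize_track(binding_track, threshold), protein.tm_segments)
    return [r.span for r in find_runs(mask, dbr_min_len)]


# --- summary table round trip -------------------------------------------------

def summary_schema(k_values: Iterable[int] = DEFAULT_K_VALUES) -> List[str]:
    ks = sorted(set(int(k) for k in k_values))
    cols = ["accession", "length", "effective_length", "disorder_content"]
    cols += [f"ldr_ratio_{k}" for k in ks]
    cols += [f"n_ldr_{k}" for k in ks]
    cols += ["dbr_ratio", "n_dbr"]
    return cols


def write_summary_table(summaries: Sequence[DisorderSummary], path) -> None:
    """Write per-protein summaries as a TSV (fractions as percentages, 2 dp)."""
    from .io import write_table

    if not summaries:
        raise ValueError("no summaries to write")
    ks = summaries[0].k_values
    rows = []
    for s in summaries:
        row = {
            "accession": s.accession,
            "length": s.length,
            "effective_length": s.effective_length,
            "disorder_content": s.disorder_content,
            "dbr_ratio": s.dbr_residue_ratio,
            "n_dbr": s.n_dbr,
        }
        for k in ks:
            row[f"ldr_ratio_{k}"] = s.ldr_residue_ratio[k]
            row[f"n_ldr_{k}"] = s.n_ldr[k]
        rows.append(row)
    percent = ["disorder_content", "dbr_ratio"] + [f"ldr_ratio_{k}" for k in ks]
    write_table(rows, path, summary_schema(ks), percent_columns=percent)


def read_summary_table(path) -> List[DisorderSummary]:
    """Read back a summary TSV written by :func:`write_summary_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ks = sorted(int(c.split("_")[-1]) for c in df.columns if c.startswith("ldr_ratio_"))
    out: List[DisorderSummary] = []
    for row in df.itertuples(index=False):
        dbr_raw = getattr(row, "dbr_ratio")
        out.append(
            DisorderSummary(
                accession=row.accession,
                length=int(row.length),
                effective_length=int(row.effective_length),
                disorder_content=float(row.disorder_content) / 100.0,
                ldr_residue_ratio={k: float(getattr(row, f"ldr_ratio_{k}")) / 100.0 for k in ks},
                n_ldr={k: int(getattr(row, f"n_ldr_{k}")) for k in ks},
                dbr_residue_ratio=None if dbr_raw == "NA" else float(dbr_raw) / 100.0,
                n_dbr=None if getattr(row, "n_dbr") == "NA" else int(getattr(row, "n_dbr")),
            )
        )
    return out
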