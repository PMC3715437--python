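"""Cohort statistics over per-protein disorder summaries.

Group/pathway summary tables, Wilcoxon rank-sum comparisons between
groups, Fisher/hypergeometric enrichment against a whole-proteome
background, the highly-disordered selection rule, and the "structured
island" classification of domains flanked by long disordered regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import BinaryMask, DisorderSummary
from .records import DomainHit, ProteinRecord, Segment

logger = logging.getLogger(__name__)

Alternative = str  # "two_sided" | "greater" | "less"
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class TestResult:
    test: str  # "rank_sum" | "enrichment"
    statistic: float
    p_value: float
    alternative: Alternative
    n1: int
    n2: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


@dataclass
class GroupSummaryRow:
    group_label: str
    n_proteins: int
    mean_disorder_content: float
    median_disorder_content: float
    mean_dbr_ratio: Optional[float]
    median_dbr_ratio: Optional[float]
    mean_ldr_ratio_30: float
    median_ldr_ratio_30: float


@dataclass
class PrevalenceRow:
    group_label: str
    n_proteins: int
    fraction_with_ldr: Dict[int, float]  # k -> fraction of proteins with an LDR >= k


@dataclass
class BackgroundCounts:
    """Whole-proteome reference counts for enrichment tests."""

    n_proteins: int
    n_with_ldr: Dict[int, int]  # k -> number of proteome proteins with an LDR >= k


def _labels_of(grouping: Mapping[str, object], accession: str) -> Tuple[str, ...]:
    labels = grouping[accession]
    if isinstance(labels, str):
        return (labels,)
    return tuple(labels)


def _by_label(
    summaries: Sequence[DisorderSummary], grouping: Mapping[str, object]
) -> Dict[str, List[DisorderSummary]]:
    out: Dict[str, List[DisorderSummary]] = {}
    for s in summaries:
        for label in _labels_of(grouping, s.accession):
            out.setdefault(label, []).append(s)
    return out


def group_summary(
    summaries: Sequence[DisorderSummary], grouping: Mapping[str, object]
) -> List[GroupSummaryRow]:
    """Mean/median disorder metrics per group label.

    A protein carrying several labels (e.g. a cargo receptor shared by
    two routes) contributes once to each label.  Medians use the
    midpoint convention for even sample sizes.  Proteins lacking a
    binding track are omitted from the DBR mean/median only.
    """
    rows: List[GroupSummaryRow] = []
    for label, group in sorted(_by_label(summaries, grouping).items()):
        if not group:
            raise ValueError(f"empty group {label!r}")
        dc = np.array([s.disorder_content for s in group])
        ldr = np.array([s.ldr_residue_ratio[30] for s in group])
        dbr = np.array([s.dbr_residue_ratio for s in group if s.dbr_residue_ratio is not None])
        rows.append(
            GroupSummaryRow(
                group_label=label,
                n_proteins=len(group),
                mean_disorder_content=float(dc.mean()),
                median_disorder_content=float(np.median(dc)),
                mean_dbr_ratio=float(dbr.mean()) if dbr.size else None,
                median_dbr_ratio=float(np.median(dbr)) if dbr.size else None,
                mean_ldr_ratio_30=float(ldr.mean()),
                median_ldr_ratio_30=float(np.median(ldr)),
            )
        )
    return rows


def ldr_prevalence(
    summaries: Sequence[DisorderSummary],
    grouping: Mapping[str, object],
    k_values: Iterable[int] = (30, 50, 100),
) -> List[PrevalenceRow]:
    """Fraction of proteins per group carrying at least one LDR of length >= k."""
    ks = sorted(set(int(k) for k in k_values))
    rows: List[PrevalenceRow] = []
    for label, group in sorted(_by_label(summaries, grouping).items()):
        if not group:
            raise ValueError(f"empty group {label!r}")
        fractions = {k: sum(1 for s in group if s.has_ldr(k)) / len(group) for k in ks}
        rows.append(PrevalenceRow(group_label=label, n_proteins=len(group), fraction_with_ldr=fractions))
    return rows


EXACT_RANKSUM_MAX_N = 12


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], alternative: Alternative = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the pooled sample is small
    (n1 + n2 <= 12) and tie-free; otherwise the normal approximation
    with midrank tie correction and continuity correction.  Two samples
    with all values identical are degenerate: p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    if alternative not in _SCIPY_ALT:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return TestResult("rank_sum", float(a.size * b.size / 2.0), 1.0,
                          alternative, a.size, b.size, degenerate=True)
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= EXACT_RANKSUM_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=_SCIPY_ALT[alternative], method=method,
                           use_continuity=True)
    return TestResult("rank_sum", float(res.statistic), float(res.pvalue),
                      alternative, a.size, b.size)


def enrichment_test(
    k_group: int,
    n_group: int,
    k_background: int,
    n_background: int,
    alternative: Alternative = "greater",
) -> TestResult:
    """Fisher-style hypergeometric test of a group count against a background.

    Models the group as ``n_group`` draws without replacement from a
    background of ``n_background`` proteins of which ``k_background``
    carry the feature; the tail beyond the observed ``k_group`` gives
    the p-value (survival function in log space via scipy).
    """
    if not (0 <= k_group <= n_group):
        raise ValueError("need 0 <= k_group <= n_group")
    if not (0 <= k_background <= n_background):
        raise ValueError("need 0 <= k_background <= n_background")
    if n_background < n_group:
        raise ValueError("background smaller than the group it contains")
    dist = sps.hypergeom(n_background, k_background, n_group)
    if alternative == "greater":
        p = float(dist.sf(k_group - 1))
    elif alternative == "less":
        p = float(dist.cdf(k_group))
    elif alternative == "two_sided":
        table = [
            [k_group, n_group - k_group],
            [k_background - k_group, (n_background - n_group) - (k_background - k_group)],
        ]
        if min(table[1]) < 0:
            raise ValueError("background counts incompatible with a nested group")
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult("enrichment", float(k_group), min(p, 1.0), alternative,
                      n_group, n_background)


@dataclass
class ComparisonEntry:
    description: str
    result: TestResult
    p_adjusted: Optional[float] = None


@dataclass
class PathwayComparisonReport:
    pairwise: List[ComparisonEntry]
    enrichment: List[ComparisonEntry]

    @property
    def entries(self) -> List[ComparisonEntry]:
        return self.pairwise + self.enrichment


def compare_pathways(
    summaries: Sequence[DisorderSummary],
    grouping: Mapping[str, object],
    background: BackgroundCounts,
    k_values: Iterable[int] = (30, 50, 100),
    rank_sum_alternative: Alternative = "two_sided",
) -> PathwayComparisonReport:
    """All pairwise rank-sum comparisons plus per-route LDR enrichment.

    Pairwise rank-sum tests compare disorder content and DBR residue
    ratio between every pair of labels; enrichment tests compare each
    label's LDR-carrier count at each k against the whole-proteome
    background (which includes the group).  Raw p-values are reported;
    a Benjamini-Hochberg adjusted column is attached for transparency,
    not used for any decision.
    """
    if background is None:
        raise ValueError("background counts are required")
    groups = _by_label(summaries, grouping)
    labels = sorted(groups)
    ks = sorted(set(int(k) for k in k_values))

    pairwise: List[ComparisonEntry] = []
    for la, lb in itertools.combinations(labels, 2):
        dc_a = [s.disorder_content for s in groups[la]]
        dc_b = [s.disorder_content for s in groups[lb]]
        pairwise.append(
            ComparisonEntry(
                f"disorder_content:{la}_vs_{lb}",
                rank_sum_test(dc_a, dc_b, rank_sum_alternative),
            )
        )
        dbr_a = [s.dbr_residue_ratio for s in groups[la] if s.dbr_residue_ratio is not None]
        dbr_b = [s.dbr_residue_ratio for s in groups[lb] if s.dbr_residue_ratio is not None]
        if dbr_a and dbr_b:
            pairwise.append(
                ComparisonEntry(
                    f"dbr_ratio:{la}_vs_{lb}",
                    rank_sum_test(dbr_a, dbr_b, rank_sum_alternative),
                )
            )

    enrichment: List[ComparisonEntry] = []
    for label in labels:
        group = groups[label]
        for k in ks:
            if k not in background.n_with_ldr:
                raise ValueError(f"background carries no LDR count for k={k}")
            k_group = sum(1 for s in group if s.has_ldr(k))
            enrichment.append(
                ComparisonEntry(
                    f"ldr_{k}_enrichment:{label}",
                    enrichment_test(k_group, len(group), background.n_with_ldr[k],
                                    background.n_proteins, "greater"),
                )
            )

    report = PathwayComparisonReport(pairwise=pairwise, enrichment=enrichment)
    entries = report.entries
    if entries:
        adjusted = multipletests([e.result.p_value for e in entries], method="fdr_bh")[1]
        for entry, padj in zip(entries, adjusted):
            entry.p_adjusted = float(padj)
    return report


@dataclass
class HighDisorderCall:
    """Per-protein evaluation of the highly-disordered selection rule."""

    accession: str
    disorder_content: float
    ldr_ratio_30: float
    passed_dc: bool
    passed_ldr: bool

    @property
    def selected(self) -> bool:
        return self.passed_dc or self.passed_ldr


def select_highly_disordered(
    summaries: Sequence[DisorderSummary],
    dc_min: float = 0.70,
    ldr_cap: float = 0.50,
    ldr_rule: str = "min",
) -> List[HighDisorderCall]:
    """Flag highly disordered proteins.

    A protein is selected when its disorder content is at least
    ``dc_min`` (default 70%) or its LDR(30) residue ratio reaches the
    cohort cutoff.  The cutoff combines "cohort mean + 2 sd" with the
    absolute ``ldr_cap`` (default 50%); ``ldr_rule`` picks how:
    ``"min"`` (either criterion suffices, the default reading) or
    ``"max"`` (both required of the cutoff).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries for a cohort mean/sd")
    ldr = np.array([s.ldr_residue_ratio[30] for s in summaries])
    adaptive = float(ldr.mean() + 2.0 * ldr.std(ddof=1))
    if ldr_rule == "min":
        cutoff = min(adaptive, ldr_cap)
    elif ldr_rule == "max":
        cutoff = max(adaptive, ldr_cap)
    else:
        raise ValueError(f"unknown ldr_rule {ldr_rule!r}")
    return [
        HighDisorderCall(
            accession=s.accession,
            disorder_content=s.disorder_content,
            ldr_ratio_30=s.ldr_residue_ratio[30],
            passed_dc=s.disorder_content >= dc_min,
            passed_ldr=s.ldr_residue_ratio[30] >= cutoff,
        )
        for s in summaries
    ]


DOMAIN_CONTEXT_LABELS = ("island_both", "island_N", "island_C", "embedded")


def classify_domain_context(
    domains: Sequence[DomainHit],
    mask: BinaryMask,
    flank_disorder_min: float = 0.70,
    min_flank_len: int = 30,
) -> List[Tuple[DomainHit, str]]:
    """Classify each domain as a structured island or embedded.

    For a domain, the N-side flank is everything from the N-terminus to
    the residue before the domain and the C-side flank everything after
    it.  A flank qualifies when its countable (non-TM) length is at
    least ``min_flank_len`` and its disorder fraction is at least
    ``flank_disorder_min``.  The label names the qualifying disordered
    side(s): ``island_N``, ``island_C``, ``island_both`` or
    ``embedded``.  Overlapping domains are classified independently.
    """
    n = len(mask)
    for a, b in itertools.combinations(domains, 2):
        if a.span.overlaps(b.span):
            logger.warning("overlapping domains %s and %s; contexts computed independently", a, b)
            break

    def flank_qualifies(lo: int, hi: int) -> bool:
        # [lo, hi] 1-based inclusive; empty when lo > hi
        if lo > hi:
            return False
        sel = slice(lo - 1, hi)
        countable = ~mask.excluded[sel]
        total = int(countable.sum())
        if total < min_flank_len:
            return False
        disordered = int((mask.flags[sel] & countable).sum())
        return disordered / total >= flank_disorder_min

    out: List[Tuple[DomainHit, str]] = []
    for dom in domains:
        if dom.span.end > n:
            raise ValueError(f"domain {dom.name} {dom.span} outside protein of length {n}")
        n_side = flank_qualifies(1, dom.span.start - 1)
        c_side = flank_qualifies(dom.span.end + 1, n)
        if n_side and c_side:
            label = "island_both"
        elif n_side:
            label = "island_N"
        elif c_side:
            label = "island_C"
        else:
            label = "embedded"
        out.append((dom, label))
    return out
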