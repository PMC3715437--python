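"""vtdisorder: comparative intrinsic-disorder analysis of vesicle trafficking proteins.

The package computes per-protein disorder metrics from per-residue
predictor score tracks (disorder content, long-disordered-region and
disordered-binding-region residue ratios, with transmembrane residues
excluded), compares protein groups and trafficking routes statistically,
filters off-pathway interaction partners, analyzes the structural
context of tissue-specific exons, compares human-yeast ortholog pairs,
and generates fully synthetic cohorts with known ground truth for
testing all of the above.
"""

from importlib import resources as _resources
from pathlib import Path as _Path

__version__ = "0.1.0"

from .records import (  # noqa: F401
    DomainHit,
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
from .io import (  # noqa: F401
    read_annotation_table,
    read_edges_table,
    read_fasta,
    read_ortholog_pairs,
    read_score_track,
    read_tse_table,
    write_score_track,
    write_table,
)
from .metrics import (  # noqa: F401
    BinaryMask,
    DisorderSummary,
    Run,
    apply_tm_mask,
    binarize_track,
    dbr_regions,
    find_runs,
    read_summary_table,
    summarize_protein,
    write_summary_table,
)
from .stats import (  # noqa: F401
    BackgroundCounts,
    TestResult,
    classify_domain_context,
    compare_pathways,
    enrichment_test,
    group_summary,
    ldr_prevalence,
    rank_sum_test,
    select_highly_disordered,
)
from .interactions import (  # noqa: F401
    FilteredPartnerSet,
    InteractionReportRow,
    filter_offpathway,
    greedy_cluster,
    interaction_report,
    pairwise_identity,
    read_interaction_report,
)
from .tse import (  # noqa: F401
    TSEStructureRow,
    analyze_tse,
    map_exon_to_protein,
    select_tses,
    tse_dbr_association,
    tse_disorder,
    tse_report,
)
from .orthologs import OrthologComparison, category_tallies, compare_orthologs  # noqa: F401
from .synth import (  # noqa: F401
    ArchitectureSpec,
    CohortSpec,
    GroupSpec,
    plant_architecture,
    propensity_track,
    synth_cohort,
    synth_tracks,
)


def data_path(filename: str) -> _Path:
    """Path of a packaged reference data file."""
    return _Path(_resources.files("vtdisorder") / "data" / filename)
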