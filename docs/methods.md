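# Methods

## Score tracks and binarization

The pipeline consumes per-residue prediction tracks in the plain-text
dialect of the common disorder/binding predictors: one line per residue
with a 1-based consecutive index, optionally the amino acid letter, and
a score in [0, 1] ('#' lines are comments).  Both 3-column and 2-column
files are accepted; when the amino-acid column is present it is
validated against the owning sequence (position-wise, with `X`
tolerated on either side).  Scores are binarized at a threshold
(default 0.5) with **score ≥ threshold counted as disordered**: the
tie-goes-to-disordered convention is a deliberate choice, exposed as a
parameter, because a residue scored exactly at the cutoff is
conventionally reported as disordered by the predictors themselves.

All coordinates anywhere in the package are 1-based and inclusive on
both ends ("230–446" style); half-open conversions are internal.
Selenocysteine and ambiguity codes (U, B, Z, X) are accepted in
sequences and scored like any residue, since curated sequence databases
contain them.

## Transmembrane exclusion and run segmentation

Residues inside annotated transmembrane segments are excluded from
every metric: they leave both the numerator and the denominator
(the *effective length*).  Run segmentation uses a **no-join policy**
by default: a maximal disordered run does not continue across an
excised TM segment, because a membrane-embedded stretch physically
interrupts a disordered region.  The alternative (TM residues
transparent, runs may span them without counting them) is available via
`find_runs(..., join_excluded=True)` for sensitivity analyses.

Long disordered regions (LDRs) are maximal runs of at least *k*
countable disordered residues, *k* ∈ {30, 50, 100} by default.
Disordered binding regions (DBRs) are the same construction on the
binding track with a minimum region length of 6 residues by default.
Real binding-region predictors apply additional internal region filters
that are not public; DBR *counts* are therefore convention-dependent
and reports should treat them as such, while DBR residue *ratios* are
robust to the exact minimum length.  The DBR ratio uses the same
TM-excluded denominator as every other metric.  A protein shorter than
*k* simply has no LDR at that *k* (not an error), and a protein without
a binding track has its DBR fields reported as unavailable (`None`/
`NA`), never as zero.

## Statistics

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney U) test:
the exact null distribution when the pooled sample is tie-free and has
at most 12 observations, otherwise the normal approximation with
midrank tie correction and continuity correction (both via
`scipy.stats.mannwhitneyu`; the test suite checks the exact branch
against full permutation enumeration).  Two samples whose pooled values
are all identical are degenerate and reported as p = 1 with a flag.
The default alternative is two-sided; one-sided alternatives are
available where a directional hypothesis is stated up front.

Enrichment of LDR-carrying proteins in a group against a whole-proteome
background uses the hypergeometric tail (Fisher's exact construction).
The 2×2 table treats the background as the *whole* proteome including
the group — reference counts are whole-proteome values, and exclusion
of the group from the background is not assumed; this is configurable
by adjusting the counts passed in.  Background sizes are runtime
parameters (`BackgroundCounts`), not constants, because published
proteome sizes vary with the release and the de-duplication applied.

No multiple-testing correction is applied to the reported p-values; a
Benjamini–Hochberg adjusted column is emitted alongside every test
report for transparency, and is not used for any decision in the
pipeline.

Medians use the midpoint convention (average of the two central order
statistics for even n).  Multi-route proteins are counted once per
route in all per-route statistics.

## Highly-disordered selection and structured islands

A protein is called highly disordered when its disorder content is at
least 70%, or when its LDR(30) residue ratio reaches a cohort cutoff
combining the adaptive "cohort mean + 2 sd" with an absolute 50%
ceiling.  The default reading is `min(mean + 2·sd, 0.50)` — either
criterion suffices — because the ceiling otherwise never binds in
high-variance cohorts; the stricter `max` reading is available by flag
and every call reports which component of the rule fired.

For domain context, a domain is a "structured island" when the region
between it and a terminus (its flank) has at least 30 countable
residues and at least 70% disorder.  The label names the disordered
side: `island_N`, `island_C`, `island_both`, or `embedded` when neither
flank qualifies.  Overlapping domains are classified independently with
a logged warning.

## Off-pathway interaction filtering

Partner edges (source protein, partner id, partner sequence, STRING-
style confidence) are filtered per source in this order: confidence
< 0.9 dropped; partners more than 70% identical to *any* protein of the
trafficking dataset dropped; surviving near-duplicate partners of the
same source collapsed by greedy longest-first clustering at the same
identity threshold (founding/longest member kept, ties broken by
identifier); partners on an exclusion-id list dropped.  Every removal
carries a machine-readable reason, and kept + removed always partition
the input.

Pairwise identity is computed as identical columns of an optimal global
alignment divided by the **shorter** sequence length — the convention
of the greedy clustering tools this step emulates.  The alignment uses
match 1 / mismatch 0 / no gap penalty, under which the optimal score
equals the maximum number of identical aligned columns (the longest
common subsequence), making the measure symmetric and
denominator-stable.  The same clustering operation at a 0.95 threshold
serves as proteome de-duplication.

The exclusion list externalizes manual curation; the packaged
`exclusion_gtpase_example.txt` lists promiscuous small GTPases of the
ARF/SAR/RAB families as a documented example and is not hard-coded
anywhere.  Off-pathway totals count (source, partner) **edges**;
unique-partner counts are emitted alongside because several sources can
share a partner.  Route means and medians are taken over all annotated
proteins of the route, including those with zero surviving partners.

## Tissue-specific exons

Coding exons with an exon switch score ≥ 0.25 are selected (non-coding
records are dropped with a logged reason).  Exon-to-protein mapping
uses a **codon-majority rule**: residue *r* (CDS bases 3r−2…3r) belongs
to an exon when at least 2 of its 3 bases fall inside it.  The rule is
deterministic, symmetric in reading direction, and tiles consecutive
exons without overlap (property-tested); a first-base rule is available
as an alternative.  A trailing partial codon is ignored with a warning,
and an exon contributing no residues (e.g. a 1-base exon) yields an
explicit empty result.  Records may instead carry a pre-mapped protein
span directly, so published span tables can be consumed verbatim.

TSE disorder is the disordered fraction of the span with TM residues
removed from both numerator and denominator — consistent with the
whole-protein metrics, so a whole-protein span reproduces the protein's
disorder content exactly.  Whether published TSE fractions excluded TM
residues is not documented; the TM-consistent convention is used here.
DBRs are split into span-overlapping and *flank-only* sets, the latter
being DBRs disjoint from the span but intersecting its 5-residue
boundary neighborhood.  Pooled TSE disorder is residue-weighted (total
disordered TSE residues over total TSE residues), not an average of
per-exon fractions.

## Ortholog comparison

For each human–yeast pair, Δ = d.c.(human) − d.c.(yeast) in percentage
points.  Pairs with max(d.c.) ≤ 30% are retained in the output but set
aside from category tallies (strictly-greater filter; exact-boundary
cases are flagged).  |Δ| < 5 percentage points is "similar" — the
difference is read in percentage points of disorder content, which is
how published similar pairs (e.g. 71.4% vs 74.44%) are described —
otherwise the pair is "human_higher" or "yeast_higher".  Swapping a
pair's members negates Δ and swaps the directional categories.

## Synthetic data generator

The generator defines the study conditions for all simulation-based
tests:

- **Architecture**: ordered/disordered/TM segments expanded into
  per-residue ground truth; binding regions must lie inside disordered
  segments.  Random architectures realize a planted disorder fraction
  with 1–3 contiguous disordered blocks (long blocks split), because
  single long blocks dominate real highly disordered trafficking
  proteins while moderate proteins carry several shorter IDRs.
- **Tracks**: disordered residues score around 0.8 and ordered around
  0.2 with truncated-Gaussian noise (default sd 0.05; 0.08 in the
  route-contrast simulations).  At these noise levels the
  misclassification probability at the 0.5 threshold is negligible
  (the centers sit 0.3 away), so planted fractions are recovered to
  within sampling error.  The noise model is a testing device only; it
  does not emulate the error structure of any real predictor, whose
  mistakes are sequence-correlated rather than independent — passing
  recovery tests therefore demonstrates correctness of the pipeline
  arithmetic, not predictor accuracy on real proteomes.
- **Cohorts**: per-protein planted disorder fractions are drawn from a
  truncated Gaussian around the group target mean.  The default
  route-contrast conditions are target means 0.28 vs 0.09 with sd 0.08
  and n = 30 per group, mirroring the clathrin-vs-COPI disorder-content
  contrast scale, with protein lengths 120–300 to keep runtimes small.
- **Sequences** are drawn from residue pools biased by structural class
  (disorder-promoting residues in disordered segments, hydrophobic
  residues in TM segments) so that the toy propensity predictor — a
  sliding-window average (window 21) of a published-style per-residue
  propensity scale, min–max squashed to [0, 1] over the scale range —
  correlates with the planted labels.  The toy predictor is an explicit
  stand-in used for generating plausible tracks; it is not a
  reimplementation of any energy-based method.

All generator outputs are byte-identical across runs with the same spec
and seed.

## Numerical and reporting conventions

- Fractions are stored in [0, 1] internally; report tables print them
  as percentages with 2 decimals, and report readers divide by 100 on
  the way back in.  Missing values are printed as `NA`.
- Table writers preserve row order and are deterministic, so re-writing
  identical rows yields byte-identical files.
- Simulation sizes in the test and acceptance suites (cohorts of 25–30
  proteins per group, 500 null replicates, 1000 random masks for the
  run-segmentation oracle) were chosen as the smallest sizes at which
  the checked properties are stable; the null calibration operates on
  the planted disorder-content draws directly (the quantity the test
  consumes), while the effect-detection check runs the full
  generate–read–summarize–test pipeline.

## Known limitations

- Absolute published group/route means, medians, prevalences and
  p-values for the real trafficking dataset are not reproducible
  without the original sequence release and predictor outputs; the
  package reproduces the *machinery* and verifies it against oracles
  and planted ground truth instead.
- DBR region counts depend on the minimum-length convention (above).
- The identity measure ignores substitution similarity (match/mismatch
  only), matching the clustering-tool convention it emulates, and is
  not a substitute for a proper alignment identity when gap placement
  matters biologically.
- The interaction filter treats partner identifiers as opaque; it does
  not resolve identifier synonymy.
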