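# vtdisorder

Comparative intrinsic-disorder analysis of vesicle trafficking proteins.

Eukaryotic vesicle trafficking is carried out by three major routes —
the clathrin-mediated system and the COPI and COPII coat systems — whose
proteins differ strongly in how much they rely on intrinsically
disordered regions (IDRs).  `vtdisorder` is a pipeline for quantifying
that reliance from per-residue disorder and binding predictions
(IUPred/ANCHOR-style score tracks) and curated annotation tables.  It is
aimed at structural bioinformaticians who want to compare disorder
metrics between protein groups, routes, species, or ortholog pairs, and
to relate disorder to moonlighting interactions and tissue-specific
splicing.

## What it computes

For each protein, after excluding annotated transmembrane (TM) residues
from every metric, scores are binarized at the standard 0.5 threshold
(score ≥ 0.5 = disordered) and three measures are taken:

- **disorder content** (d.c.) — disordered residues / non-TM residues;
- **LDR residue ratio** — residues in Long Disordered Regions, i.e.
  maximal runs of ≥ *k* consecutive disordered residues (*k* = 30, 50,
  100), / non-TM residues;
- **DBR residue ratio** — the same construction over the binding track,
  giving residues in Disordered Binding Regions (segments predicted to
  fold upon partner binding).

On top of the per-protein metrics the package provides:

- group/route summary tables (means, medians, LDR-carrier prevalences),
  Wilcoxon rank-sum comparisons between groups (exact enumeration for
  small tie-free samples, tie-corrected normal approximation otherwise)
  and Fisher/hypergeometric enrichment against a whole-proteome
  background, with a Benjamini–Hochberg column attached for reference;
- the highly-disordered selection rule (d.c. ≥ 70% or LDR ratio above a
  cohort-adaptive cutoff) and a "structured island" classifier for
  domains flanked by long disordered regions;
- a two-step off-pathway interaction-partner filter (confidence ≥ 0.9;
  removal of partners > 70% identical to any pathway protein; greedy
  longest-first clustering of near-duplicate partners; exclusion lists
  for curated removals) and per-route interaction reports;
- tissue-specific-exon (TSE) structural analysis: exon switch-score
  selection (≥ 0.25), codon-majority mapping of CDS exons onto protein
  residues, TSE disorder content, and DBR association including a
  5-residue boundary neighborhood rule;
- human–yeast ortholog disorder comparison (pairs with ≤ 30% disorder
  in both members set aside; |Δd.c.| < 5 percentage points = similar);
- a synthetic-data generator that plants
  ordered/disordered/TM/binding-region architectures with controlled
  group effect sizes and bounded score noise, so the whole pipeline is
  testable without any external predictor or download.

## Worked example (library)

```python
import numpy as np
from vtdisorder import ProteinRecord, ScoreTrack, Species, summarize_protein
from vtdisorder.records import TrackKind

protein = ProteinRecord(accession="DEMO1", name="DEMO1",
                        species=Species.HUMAN, sequence="A" * 248)
scores = np.concatenate([np.full(149, 0.9), np.full(99, 0.1)])
summary = summarize_protein(protein, ScoreTrack(TrackKind.DISORDER, scores))
print(f"disorder content: {100 * summary.disorder_content:.2f}%")
print(f"LDR(30) residue ratio: {100 * summary.ldr_residue_ratio[30]:.2f}%")
print(f"number of LDRs (>=30): {summary.n_ldr[30]}")
```

prints

```
disorder content: 60.08%
LDR(30) residue ratio: 60.08%
number of LDRs (>=30): 1
```

— a 248-residue protein with 149 predicted-disordered residues has
149/248 = 60.08% disorder content, and because those residues form one
continuous N-terminal stretch, the same fraction sits in a single LDR.

## Worked example (CLI)

```bash
cat > spec.yaml <<'YAML'
seed: 7
noise_sd: 0.05
groups:
  - {label: CLTR, n_proteins: 25, target_mean_dc: 0.28, dc_sd: 0.08, length_range: [120, 300]}
  - {label: COPI, n_proteins: 25, target_mean_dc: 0.09, dc_sd: 0.08, length_range: [120, 300]}
YAML
vtdisorder synth --spec spec.yaml --out cohort
vtdisorder metrics --fasta cohort/cohort.fasta \
    --disorder-dir cohort/tracks/disorder --anchor-dir cohort/tracks/anchor \
    --annotations cohort/annotations.tsv --out summary.tsv
printf 'n_proteins\t1000\nn_with_ldr_30\t456\nn_with_ldr_50\t331\nn_with_ldr_100\t182\n' > background.tsv
vtdisorder stats --summaries summary.tsv --fasta cohort/cohort.fasta \
    --annotations cohort/annotations.tsv --background-counts background.tsv --out stats
```

`stats/routes_summary.tsv` then contains (percentages, 2 decimals):

```
group_label  n_proteins  mean_disorder_content  median_disorder_content  ...
CLTR         25          28.12                  27.97
COPI         25          10.94                  11.29
```

and `stats/pathway_tests.tsv` reports the route contrast

```
disorder_content:CLTR_vs_COPI  rank_sum  578.00  2.72e-07  ...
```

i.e. the generator planted mean disorder contents of 0.28 vs 0.09 and
the pipeline recovers them (28.12% vs 10.94%) and finds the contrast
highly significant.  The remaining subcommands (`interactions`, `tse`,
`orthologs`) consume the documented TSV formats; see `--help` on each.

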