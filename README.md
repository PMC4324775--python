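# splicescape

Alternative-splicing discovery for compact fungal-style genomes: from spliced
paired-end alignments (or simulated junction counts) to a refined
splice-junction catalog, a complete event taxonomy with intron-retention
statistics, and the downstream feature and isoform-frequency analyses.
A first-class synthetic-data generator plants genes, introns, branch points
and splicing events with known truth, so every stage runs and is testable
with no external data.

Intended users: people analysing deep RNA-seq of intron-dense genomes
(fungi and other microbial eukaryotes, where introns are short — tens of
base pairs — and intron retention dominates alternative splicing), and
people who need a controlled simulator to benchmark splicing callers.

## What it computes

**Junction catalog.** A splice junction (SJ) is an intron span
(chromosome, strand, start, end) supported by ≥ 2 uniquely mapped read
pairs. Each intron is annotated with:

* a branch point, found by hierarchical motif search — the 3'-most instance
  of CURAY (primary), then UURAY (secondary), then a degenerate YURAY family
  in which the first, third or fifth position is free; the branch point is
  the adenosine at the fourth motif position;
* a polypyrimidine tract — the 3'-most window of six consecutive non-adenine
  bases containing ≥ 3 uridines, maximal in T count;
* raw log-odds scores for the donor (13-base window: 3 exonic + 10
  intronic), acceptor (17-base: 14 intronic + 3 exonic) and branch (11-base)
  windows. For a position-frequency matrix `f` the score of a window
  `x₁…x_L` is `Σ_i log₂(f_i(x_i) / 0.25)` — no pseudocounts, no rescaling.

Junctions with no branch point, or with the branch A more than 60 bp from
the 3'ss, are removed; same-length overlapping junction pairs with starts
within 10 bp (an alignment-error signature) are collapsed onto the
higher-scoring donor, transferring support; introns containing N are
dropped.

**Event taxonomy.** Junctions are clustered by intron-span overlap
(single linkage, mixed-strand clusters excluded). Singleton clusters are
retained introns (IR) when any intronic base has read coverage, else
constitutive (IC); the intron retention ratio is

    IRR = median per-base intronic coverage / junction support,

binned [0, 0.01), [0.01, 0.1), [0.1, 1), [1, ∞). Two-junction clusters are
A5SS (shared acceptor), A3SS (shared donor), "A5SS and A3SS" (nested) or
"A5SS or A3SS" (staggered); larger clusters are MA5SS(k)/MA3SS(k), the
three-junction exon-skipping pattern, or COMPLEX with a pairwise-label code.

**Downstream statistics.** Per-intron features (length, GC, three scores)
by class and IRR bin; two-sided Mann-Whitney-Wilcoxon class comparisons;
isoform relative frequencies of two-junction clusters and OLS regression of
the log frequency ratio on the class-relevant score difference
(Δ5'ss for A5SS, Δ3'ss for A3SS, Δ(sum) for the combined classes).

**Transcript models.** Coverage-defined transcriptionally active regions
(> 35 bp, every base ≥ 4 reads) linked by read pairs into transcript units
(> 150 bp, mean depth ≥ 10); read pairs merged into artificial reads
(embedding at most one interval junction) and overlap-chained into models
(≥ 100 bases, every base ≥ 2 reads), with six-frame longest-ORF annotation
and screening against reference gene models and structural RNAs.

## Worked example

Run the whole pipeline on a simulated transcriptome (150 genes on three
200 kb chromosomes, introns with median length 72 bp, an intron-retention-
dominant event mix, two samples at 60 read pairs per junction):

```bash
cat > pipe.yaml <<EOF
mode: synthetic
seed: 1
EOF
splicescape run-all --config pipe.yaml --outdir out/
```

which prints the event accounting:

```json
{
  "as_cluster_ratio": 0.7522727272727273,
  "multi_MA3SS(3)": 1,
  "n_AS_events": 331,
  "n_AS_genes": 144,
  "n_IC": 109,
  "n_IR": 312,
  "n_clusters": 440,
  "n_multi": 1,
  "n_single": 421,
  "n_two_sj": 18,
  "two_sj_A3SS": 10,
  "two_sj_A5SS": 6,
  "two_sj_A5SS_AND_A3SS": 1,
  "two_sj_A5SS_OR_A3SS": 1
}
```

Reading this: the 460 simulated junctions collapse into 440 overlap
clusters; 421 are single introns, of which 312 show intronic coverage
(retained introns) and 109 are constitutive; 18 clusters hold two junctions
(6 alternative donors, 10 alternative acceptors, 1 nested, 1 staggered) and
one holds three junctions sharing a donor (MA3SS(3)). Everything except the
constitutive introns is an alternative-splicing event: 331 of 440 clusters
(75.2%) — matching the planted class mix. `out/` additionally holds
`junctions.tsv` (per-junction annotation and scores), `matrices.tsv` (the
PWMs), `ir.tsv` (IRR and bins), `features.tsv`, `comparisons.tsv`,
`isoforms.tsv`, `regressions.tsv` and `manifest.json`; runs with the same
seed are byte-identical.

The same stages are available as library calls (`splicescape.run_pipeline`,
`splicescape.junction_catalog`, `splicescape.as_classifier`, …) and as the
subcommands `simulate`, `filter-align` and `junctions`.

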