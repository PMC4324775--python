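# Methods

## The analysis in brief

The package reconstructs an alternative-splicing (AS) landscape from spliced
paired-end RNA-seq evidence in three layers: a refined splice-junction (SJ)
catalog, an exhaustive event taxonomy over junction clusters, and feature /
isoform-frequency statistics. It targets intron-dense genomes of the kind
found in filamentous fungi: introns are short (median ≈ 72 bp), splice
signals are compact (donor GT..AG with rare GC-AG and AT-AC variants, a
branch point ~15 bp from the 3'ss), and intron retention is by far the most
common AS class. All coordinates are 1-based inclusive internally;
0-based half-open conversion happens only in the bedGraph/BED writers.

## Alignment filtering

Input pairs are kept when uniquely mapped (one reported placement; NH tag
absent or 1), on one chromosome, with a mate interval < 5000 bp. Negative
intervals (overlapping mates) are allowed only when the overlapping
alignments agree base for base. The transcript strand is inferred per skip
from the donor-acceptor dinucleotides; pairs whose mates imply opposite
strands are rejected. Anchor trimming removes terminal aligned blocks
shorter than 5 bp, and trims read ends that extend at most 6 bases into a
candidate intron when the terminal anchor is longer than 12 bp. The 6-bp
proximity rule is applied geometrically at both read ends (the
acceptor-near-5'-end and donor-near-3'-end formulations are mirror images);
trimming iterates to a fixpoint, making the operation idempotent. The >12 bp
condition is read as a predicate on the anchor length before trimming — the
reading consistent with trimming a 4-base overhang off a 15-base anchor —
and is isolated in one function (`_proximity_trim_allowed`) so the
alternative reading is a one-line change.

## Junction catalog

Junctions are distinct (chromosome, strand, intron span) triples with pooled
support ≥ 2 read pairs (a pair counts once per junction even if both mates
span it). Intron sequences are handled in transcription orientation.

Branch-point search is hierarchical: the 3'-most instance of CURAY, else of
the secondary motif (UURAY by default), else of the degenerate family
{NURAY, YUNAY, YURAN}; the branch point is the fourth motif position. Two
sources give different secondary motifs (UURAY vs UUARY); UURAY is the
default because it is the natural relaxation of CURAY used in the fungal
branch-site literature, and the motif is a configuration string so the other
choice is one argument away. The search region excludes the final two
intron bases so the acceptor dinucleotide can never be consumed by a motif.
The polypyrimidine tract is the 3'-most window of six consecutive
non-adenine bases with ≥ 3 T, maximal T count winning before position; a
tract is "between 5'ss and branch" when its last base precedes the branch A
and "between branch and 3'ss" when its first base follows it (a window can
never contain the branch A, which windows exclude by the no-A rule, so the
3'-end assignment for straddling windows is vacuous but stated).

Refinement applies, in order: branch presence; branch-to-3'ss distance
≤ 60 bp; overlap correction — same-strand junction pairs of identical
length, overlapping, with starts within 10 bp are treated as alignment
errors, the lower-5'ss-score form deleted and its support transferred to
the survivor (ties: higher pooled support, then the 5'-most junction — the
source procedure is silent on ties, so determinism dictated the rule);
N exclusion. The filter report satisfies
`n_final = n_input − n_no_branch − n_branch_too_far − n_overlap_corrected −
n_n_excluded` by construction.

## Splice-site scoring

Windows: donor 13 bases (3 exonic + 10 intronic), acceptor 17 bases
(14 intronic + 3 exonic), branch 11 bases (6 up, A, 4 down), all anchored at
the boundary or branch A and strand-oriented. Introns shorter than a
window's intronic span, or windows off the chromosome end, are flagged
unscorable rather than padded. Frequencies are plain counts/total per
column, deliberately without pseudocounts: matrices are built from all
junctions, which in realistic catalogs leaves no empty cell; a zero
frequency maps to a −∞ sentinel and any window hitting it is flagged and
excluded from feature statistics. Scores are raw base-2 log-odds sums
against a uniform 0.25 background — no rescaling path exists anywhere
downstream. Scoring is two-pass: a 5'ss matrix built on the branch-filtered,
pre-correction set drives the overlap correction; final matrices and scores
are rebuilt on the corrected catalog.

## Event classification

Clusters are single-linkage components under "intron spans share ≥ 1 base on
the same chromosome"; components containing both strands are dropped and
counted. Donor and acceptor are taken in transcription orientation, so the
genomic roles of shared start/end swap on the minus strand. Singletons are
IR when any intronic base has pooled coverage ≥ 1, else IC; IRR = median
intronic coverage / pooled support (even-length medians are the mean of the
central pair), binned left-closed into [0,0.01), [0.01,0.1), [0.1,1) and
[1,∞) — the fourth bin exists because median intronic coverage can exceed
junction support. An IR is "high coverage" when every intronic base has
coverage ≥ 2. IRR uses pooled support and pooled coverage across samples
(one IRR per intron; per-sample tracks stay available). Pairs are A5SS /
A3SS / nested ("A5SS and A3SS") / staggered ("A5SS or A3SS"); ≥3-junction
clusters are MA5SS(k)/MA3SS(k) on a fully shared acceptor/donor, the exact
three-junction exon-skipping pattern, else COMPLEX coded
`n=k;A5SS=a;A3SS=b;AND=c;OR=d` from all pairwise labels. Clusters larger
than three containing a skipping sub-pattern remain COMPLEX — the
taxonomy's skipping definition is exactly three junctions. An AS gene is any
model whose span overlaps ≥ 1 junction of an AS cluster, counted once;
multiexonic means ≥ 2 annotated exons, taken from the annotation unchanged.

## Transcript models

Transcriptionally active regions are maximal runs strictly longer than 35 bp
with every base ≥ 4 reads; depth counts filtered read-pair aligned bases,
not artificial-read fill. Units are TAR components linked by pairs (a pair
links every TAR its blocks touch), kept when strictly longer than 150 bp
with mean depth ≥ 10 over TAR bases. Artificial reads merge overlapping
mates, fill sub-5 kb junction-free intervals as exonic, and embed exactly
one interval junction when interval − junction length < 85 bp (the raw mate
gap minus the junction span — the other reading of "interval" is isolated in
the same predicate). Assembly chains overlapping reads only when their
junction content agrees in the shared region (blocks chimeras); contigs are
trimmed to ≥ 2-read support, split at unsupported holes (junction holes are
kept as introns), and dropped under 100 exonic bases. Models carved from
one read component are partial models of one locus and re-link across gaps
≤ 30 bp; distinct loci link across gaps ≤ 10 bp (both inclusive,
end-to-start genomic distance). The longest ORF is taken over six frames —
three when an embedded junction's donor-acceptor pair fixes the strand —
pairing each ATG with the nearest in-frame stop (complete) or the model end
(partial); models code at > 30 aa. Reference screening drops models
overlapping reference genes by > 10 bp or structural RNAs at all.

## Downstream statistics

Intron classes for feature analysis: IC, IR (singleton clusters) and IA−IR
(members of any multi-junction cluster). Class comparisons use the
two-sided Mann-Whitney-Wilcoxon test (scipy; exact for small tie-free
samples, normal approximation with tie correction otherwise); identical
multisets return p = 1. Raw p-values are reported with no multiplicity
correction, matching how such comparisons are conventionally presented.
Isoform relative frequencies are per sample and pooled; the frequency-ratio
logarithm is natural (the slope's base is recorded in the output; r² is
base-invariant), clusters with a zero isoform count are excluded from the
regression (no pseudocount — noted in the output metadata), and a pair type
with fewer than three usable clusters or a zero-variance regressor yields an
explicitly undefined regression.

## Synthetic data: what it emulates, what it does not

The generator plants non-overlapping multi-exon genes (uniform 2–6 exons of
80–300 bp by default) on uniform-GC background chromosomes. Introns are
lognormal with median 72 bp (shape 0.45, floor 30 bp — the floor keeps room
for donor consensus, branch window and acceptor; it shifts the realized
median by well under 10%), GC ≈ 49%, donor GTAAGT / acceptor TAG consensus
with GC-AG at 1.7% and AT-AC at 0.5%, a branch point ~15 bp (sd 4) from the
3'ss and a planted polypyrimidine tract where room allows.

Three generator choices matter for interpreting test results:

* **Planted branch points always carry an intact CURAY core.**
  `consensus_strength` degrades the degenerate motif positions (R, Y) and
  the extended donor/acceptor consensus, never the core: a planted branch
  that matched no motif tier would have no recoverable truth position, so
  "recovery" would be undefined rather than failed. Accidental motif
  instances 3' of a planted branch are scrubbed (their anchor A mutated,
  iterating to a fixpoint) so the planted position is the 3'-most instance
  by construction. Branch-recovery rates therefore measure the search, not
  motif decay.
* **Every planted junction receives a support floor of 2 reads** (the
  catalog's own detectability threshold), with the overdispersed remainder
  on top; means are preserved at default depths. A planted AS event whose
  minor isoform was never sequenced is not a recoverable truth event, so
  label-recovery rates measure classification, not binomial tail luck.
* **Isoform usage is logistic in a planted score difference**:
  δ ~ N(0, 1.5) truncated to |δ| ≤ 2.5 (both isoforms observable at finite
  depth), usage p = logistic(β·δ) with β = 1 by default, and the planted
  per-junction site strengths (±δ/2 on the class-relevant site) are stored
  in the truth set. Slope-recovery analyses regress realized log count
  ratios on these planted strengths; PWM scores learned from the data
  cannot equal an externally planted δ, so this recovers the count
  allocation and regression machinery, not the PWM itself.

Counts are negative-binomial (dispersion 10) at 60 read pairs per junction
per sample over two samples by default; per-junction read depth is a free
parameter of the simulation, chosen as a typical deep-RNA-seq support level
for a highly expressed compact genome. Retained-intron coverage is drawn
per base at mean IRR × pooled support (planted IRR log-uniform on
[0.001, 2], which places roughly a third of IR events below IRR 0.01 and
two thirds below 0.1); constitutive introns get exactly zero intronic
coverage. Exonic coverage is drawn independently of the emitted reads; the
optional SAM rendering (75 bp reads, one spliced mate per junction pair,
no quality strings) is a minimal consistent view for exercising the
SAM-input path, not a read-level error model.

Not emulated: sequencing errors and quality scores, multi-mapping,
expression-level variation between genes, overlapping genes, pre-mRNA
contamination gradients, genomic DNA background. Passing recovery tests
therefore show the machinery is correct under clean planted signal; they do
not bound error rates on real libraries, where alignment noise and
coverage heterogeneity dominate.

One RNG stream per (purpose, seed) — genome, gene structures, events, reads
— so adding draws to one stage does not perturb another; all outputs are
byte-identical across runs with the same seed.

## Problem sizes and numerical conventions

Default simulation: 150 genes / ~440 introns on 3 × 200 kb chromosomes;
the usage-link regression uses a 400-gene, ~1400-intron run planting ≥ 300
alternative-donor events; PWM convergence is checked at 10,000 windows
(per-column L1 < 0.05). Tie-breaks and degenerate inputs are all stated in
the relevant sections above; floats are written with %.6g so output files
are reproducible byte for byte.

## Known limitations

* "Uniquely mapped" relies on the NH tag or single placement; aligners that
  report neither are treated as unique.
* The overlap correction assumes at most small chains of same-length
  shifted junctions; pathological long chains resolve deterministically but
  order-of-merge effects on transferred support are possible in ties.
* The assembler is an overlap-chaining reconstructor adequate for compact
  genomes at moderate depth; it makes no attempt at isoform-level assembly
  or quantification.
* Real-mode inputs require SAM (not BAM) and uncompressed FASTA/GFF3;
  bedGraph coverage reading needs chromosome lengths (taken from the FASTA).
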