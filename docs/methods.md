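# Methods

`chimerabench` is a self-contained benchmark for supervised classification of
chimeric RNA (chRNA) junctions. It simulates everything it needs — an
annotated genome, mutated copies of it carrying fusion genes, RNA-seq reads
with per-read ground truth — then detects candidate chimeric junctions from
k-mer location/support profiles and measures how well standard classifiers
separate true junctions from artefacts, at the level of single reads and of
aggregated events. This note records the models, the defaults and the
reasoning behind the open design choices.

## Synthetic reference

The reference factory emits chromosomes of i.i.d. uniform bases carrying
three structural ingredients the rest of the pipeline depends on:

- **multi-exon genes** (default 150 genes on two 1 Mb chromosomes, 3–8 exons
  of 80–400 bp separated by introns of 200–2000 bp, half on the minus
  strand). One transcript per gene; no alternative isoforms.
- **repeats**: exact copies of segments sampled *inside coding genes*,
  pasted into intergenic space until `repeat_fraction` (default 4%) of the
  genome is duplicated. Sampling sources inside genes is deliberate:
  transcript reads must be able to touch ambiguous sequence, because
  multi-location anchors are the main engine of false chimera candidates.
- **pseudogenes** (default 6% of genes): intronless copies of a coding
  gene's spliced sequence placed elsewhere, biotype `pseudogene`. They give
  the event-level artefact filter a real target.

Coordinates are 0-based half-open in memory, 1-based inclusive in GTF.
Repeat intervals are written as `repeat_region` GTF features so the bundle
round-trips losslessly through FASTA + GTF. Base composition is a uniform
null — no GC structure, no isochores; the ambiguity the profiler needs comes
entirely from the explicit repeats and pseudogenes.

## Genome mutation

Substitutions are drawn independently per position at rate 0.001 (one per
1,000 nt), the new base uniform over the three alternatives. Indels are
drawn at rate 0.0001, insertion/deletion equiprobable, lengths uniform on
[1, 15], inserted bases uniform. A position carries at most one record;
colliding draws are re-drawn, so the record set is invertible.

Translocations are reciprocal exchanges between two distinct multi-exon
coding genes: one internal exon boundary is chosen uniformly in each gene
and the genomic tail of each gene (from the first non-retained exon start)
is swapped with the other's, producing two fusion genes whose spliced
transcripts join intact exons only — exons are never split. Breakpoints are
recorded in reference coordinates: `breakpoint5` is the half-open end of the
last retained 5' exon, `breakpoint3` the start of the first retained 3'
exon. A gene participates in at most one event; deletions are forbidden
from crossing breakpoint boundaries so truth stays self-consistent. Partner
genes are restricted to the forward strand: the simulated fusion
transcripts are forward-encoded, and forward-only donors keep the segment
swap and breakpoint bookkeeping exact without reverse-complement surgery.
Minus-strand genes still exist and are expressed, so minus-strand mapping
and strand-discordant (class 3) candidates occur through the mate-2 reads.

The mutated genome is haploid — no heterozygosity, CNV or subclonality. A
liftover table maps every retained reference base to its mutated
coordinate; fusion genes appear in the lifted annotation with concatenated
exon chains, replacing their two donor genes.

## Read simulation

Expression assigns expected counts proportional to `rank^-0.6` over a
random 85% of transcripts (pseudogenes excluded — transcribed pseudogenes
are not modelled; they act purely as mapping decoys). Fusion transcripts
compete in the same pool, so a fusion gene is not necessarily expressed nor
covered. Fragments are Normal(250, 50) truncated to [read_length,
transcript length]; mates are 100 bp (200 bp supported) from either
fragment end, mate 2 reverse-complemented; sequencing noise is a uniform
0.2% per-base substitution. These are declared stand-ins for a full
short-read simulator: there are no quality-cycle effects, PCR duplicates,
intron retention or strandedness, so passing tests say nothing about those
artefact classes.

A read pair is labelled chimeric when either mate covers a fusion junction
with at least `min_overhang` (default 1) base on each side; the junction
offset inside each mate is recorded in the read name and a sidecar TSV.
Detectability effectively starts at overhang ≥ k, since the profiler needs
a mapped anchor k-mer on both sides.

The default library is 50,000 pairs per genome. This desk-scale depth keeps
the full five-genome study in minutes; all acceptance quantities are rates
and classification metrics, never absolute counts, which do not survive
scaling and are out of scope.

## Break profiling

The profiler indexes the *reference* genome's k-mers (default k = 22, a
CRAC-family convention balancing specificity and coverage at 100 bp reads)
and, for each read k-mer, records its exact-match locations on either
strand (location profile) and its occurrence count over the whole read
collection (support profile). "Unmapped" means zero exact locations — no
mismatch tolerance, so substitutions manifest as short spurious breaks,
exactly the negatives the classifier must learn.

A break is a maximal run of location-less k-mers; runs separated by at most
`merge_gap` = 2 mapped positions merge, counting `n_merged`. An error-free
junction yields a run of exactly k−1 k-mers — unless the first base across
the junction coincides with the reference continuation (junction
micro-homology), which legitimately shortens the break; the closed-form
tests therefore construct homology-free junctions.

Anchors are the nearest mapped flank k-mers; among multiple locations the
smallest (chrom, pos, strand) is taken. No cross-anchor reconciliation is
attempted — a repeat-ambiguous anchor resolving to the wrong copy is
precisely how false chimera candidates arise. Junction sides are the
anchor's junction-proximal bases. Classification of the anchor pair:
different chromosome → chimera candidate (class hint 1); different strand →
hint 3; colinear with negative gap or gap beyond `readthrough_max` = 1 Mb →
hint 2; colinear gap in [50, 300000] → splice; anything else (tiny colinear
gaps from SNVs/indels/errors, read-through distances, missing anchors) →
unresolved. The intron bounds and read-through cut-off are configurable
defaults, not biological claims.

Eight features per chimera candidate, computed on the break's support
values s (quartiles by linear interpolation, the common type-7 default):

| feature | definition |
|---|---|
| `score_break_length` | break width / (k−1) |
| `score_nb_merge` | number of merged elementary runs |
| `score_break_variance` | IQR(s) |
| `score_is_duplicate` | 1 if either anchor has >1 genomic location |
| `score_has_repeat` | 1 if any flank k-mer is multi-copy or overlaps a flagged repeat |
| `coefficient_variation` | sd(s)/mean(s) |
| `mean_amplitude` | mean flank support (≤ k mapped positions/side) − mean(s) |
| `coefficient_dispersion_interquartile` | (Q3−Q1)/(Q3+Q1) |

`mean_amplitude` is a declared interpretation — the support *drop* at the
junction relative to its flanks. `score_has_repeat` is computed but excluded
from the default modelling set: on these synthetic genomes it is nearly
constant and carries no discriminative power. The default modelling set is
the three most discriminative features: `score_is_duplicate`,
`coefficient_variation`, `score_break_length`.

A candidate is labelled TRUE when its read is a truth-chimeric read *and*
the called junction sides match the truth breakpoints within 5 bp
(unordered, so mate-2 views match too). Mislocalised calls on chimeric
reads — e.g. a break merged with a nearby splice junction — are labelled
FALSE: they are genuine detector errors and useful hard negatives.

## Read-level classification protocol

Duplicate rows collapse first: reads covering the same junction share the
same break k-mers, hence identical features (TRUE rows are unique per
(event, feature vector); FALSE rows per (junction, feature vector)). That
is why the unique/all ratio is a few percent while the unique tables keep
roughly a 17–22% TRUE minority — the imbalance regime the study targets.

Progressive sampling pools genomes 1..X into run rX. Each run is split
2/3–1/3 at random (non-stratified), three times; with five genomes that is
fifteen performance points per method. Four classifiers — KNN, RBF-SVM,
random forest (500 trees), gradient boosting — are tuned by 10-fold
stratified cross-validated AUC over small grids (KNN k ∈ {5,7,9,11}; SVM
C ∈ {0.25,1,4} × median-heuristic widths ×{0.5,1,2}; RF max_features ∈
{1,2,3}; GBM depth {1,2,3} × trees {50,100,150}, learning rate 0.1), then
refit. Grids are ordered simplest-first so CV ties resolve to the simpler
model. Confusion metrics use the conventional 0.5 threshold; AUC is the
Mann–Whitney rank statistic with ties at 0.5, and kappa is
(p_o−p_e)/(1−p_e) — both implemented directly and cross-checked against
brute force and scikit-learn in tests. Class imbalance is left as-is: no
resampling.

Because the synthetic false candidates are dominated by repeat-ambiguous
anchors, `score_is_duplicate` separates the classes strongly and the
scaled-down metrics sit above the high nineties. Passing therefore shows the
pipeline's machinery is sound under the stated conditions; it does not show
that real RNA-seq chimeras are this separable.

## Event level

The chimera score of a candidate is the read-level random forest's
predicted probability (a deliberate, documented substitution for rule-based
score refinement). Candidates with score ≥ 0.7 — the default compromise
between precision and discovery — are aggregated by single-linkage
clustering of junction side-pairs within 5 bp on both sides (sides compared
unordered); event coordinates are per-side medians, and the sum of event
supports always equals the number of filtered candidates.

Events are classed on the Gingeras taxonomy: 1 inter-chromosomal, 3 same
chromosome opposite strands, 2 same chromosome and strand (this class
covers both inverted genomic order and colinear distances beyond the
read-through bound, the only same-strand candidates that survive the splice
filter). Class 4 (different alleles) is never emitted: the simulation is
haploid and the detector has no phasing. Annotation then reclassifies:
a side inside a pseudogene → artefact (checked first, so pseudogene hits
never masquerade as splicing); both sides in one gene → splicing; otherwise
chimera, flagged `intergenic` when a side is unannotated.

Three event features feed the same classification protocol:
`coefficient_variation` of the break support pooled across supporting
reads, `fusion_distance` (|posA−posB|, sentinel 2^31−1 for
inter-chromosomal events), and `junction_support` (read count). Event truth
is a tolerance match (5 bp, unordered) against the fusion table. The
threshold sweep reports TP/FP, precision (PPR) and FDR at read and event
level for scores {0, 0.7, 0.9, 0.95, 0.99}; events are scored on an
independent genome simulated with a fresh seed and the final-run models,
so sweep precision is held-out.

## Problem sizes and numerical choices

Defaults (the study conditions): 2 × 1 Mb chromosomes, 150 genes, 8
translocations and 50k read pairs per genome, 5 genomes + 1 independent,
k = 22, 3 repeated splits. The full study runs in minutes on one CPU. All
randomness flows from one master seed through `numpy.random.SeedSequence`;
pre-model stages are byte-reproducible, model fits are deterministic given
their seeds. Degenerate situations are handled explicitly: single-class
training splits are re-drawn with a warning, zero-variance features are
dropped with a warning, single-class test sets report AUC/kappa as missing,
transcripts shorter than a read are skipped with a warning, and empty
candidate sets propagate as empty tables.

## Known limitations

- The generator's realism is deliberately minimal (uniform bases, uniform
  errors, one isoform per gene); conclusions transfer to real data only at
  the level of mechanism, not of absolute performance.
- False candidates arise almost entirely from repeat ambiguity plus
  substitution breaks; reverse-transcription template switching, the major
  in-vitro chimera source, is not modelled.
- Only classes 1–3 events can occur; class 4 requires diploidy.
- Absolute candidate/event counts depend on depth and are not comparable
  across scales; only rates and ranking metrics are.
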