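# chimerabench

A self-contained benchmark for supervised classification of chimeric RNAs
(chRNAs) — transcripts that join sequence from two distinct genomic loci,
such as the fusion transcripts produced by reciprocal translocations in
cancer. Detecting chRNAs from RNA-seq is plagued by false positives from
repeats, sequencing errors and mapping artefacts, and the field lacks a
common benchmark with ground truth. `chimerabench` builds one from scratch:
it simulates annotated genomes, mutates them with fusion translocations,
generates truth-bearing paired-end reads, detects candidate junctions from
k-mer profiles, and evaluates standard classifiers at the read and event
level. It is aimed at method developers who want a controlled, reproducible
test bed rather than at clinical fusion calling.

## The method in brief

**Simulation.** A synthetic reference (multi-exon genes, exact repeat
copies, intronless pseudogenes) is mutated with SNVs at rate 10⁻³, indels
at 10⁻⁴ (lengths uniform on [1, 15]) and reciprocal translocations that
exchange the 3′ part of one gene with the 5′ part of another at annotated
exon boundaries, never splitting an exon. RNA-seq reads are drawn from a
power-law expression profile with normal fragmentation and uniform base
errors; every read pair records whether (and where) it spans a fusion
junction.

**Detection.** For each read, every k-mer (k = 22) gets its exact-match
genomic locations and its occurrence count in the read collection. A
*break* — a maximal run of location-less k-mers — marks a putative
junction; an error-free junction gives a run of exactly k − 1. Breaks with
discordant flanking anchors (different chromosome, order or strand) become
chimera candidates; colinear intron-sized gaps are splices. Eight features
summarise each break, e.g. break length / (k − 1), anchor ambiguity, and
the coefficient of variation of the support inside the break.

**Classification.** Candidates are deduplicated and fed to KNN, RBF-SVM,
random forest and gradient boosting under a progressive-sampling protocol:
run rX pools X genomes, each split 2/3–1/3 three times, models tuned by
10-fold cross-validated AUC. Performance is ACC, sensitivity, specificity,
Cohen's kappa κ = (p₀ − pₑ)/(1 − pₑ) and AUC. The random forest's
probability then serves as a per-read *chimera score*: candidates above a
threshold (default 0.7) aggregate into events, which are classified on the
Gingeras taxonomy (class 1 inter-chromosomal, 2 order-discordant, 3
strand-discordant), reclassified against the annotation (same gene →
splicing, pseudogene → artefact), and swept over score thresholds to trace
precision (PPR = TP/(TP+FP)) against FDR.

## Worked example

```python
from chimerabench import (
    ReferenceSpec, build_reference, mutate_genome, MutationRates,
    assign_expression, simulate_reads, GenomeKmerIndex,
    ProfilerParams, collect_read_features, deduplicate,
)
from chimerabench.profiler import build_support, TOP3

spec = ReferenceSpec(n_chroms=2, chrom_length=300_000, n_genes=60,
                     repeat_fraction=0.04, pseudogene_fraction=0.07)
reference = build_reference(spec, seed=7)
index = GenomeKmerIndex(reference.sequences, k=22)

mutated = mutate_genome(reference, MutationRates(), n_translocations=4, seed=11)
profile = assign_expression(mutated.lifted_genes, library_size=20_000, seed=12)
reads = simulate_reads(mutated, profile, n_pairs=20_000, seed=13)

support = build_support(reads, k=22)
table = collect_read_features(reads, index, support, mutated.fusions,
                              reference.repeats, ProfilerParams())
unique = deduplicate(table)
print(f"{len(table)} candidate junctions from {2 * len(reads)} mates; "
      f"{len(unique)} unique ({unique['label'].mean():.1%} true chimeras)")
print(unique.groupby("label")[TOP3].mean().round(3).to_string())
```

prints

```
556 candidate junctions from 40000 mates; 383 unique (37.3% true chimeras)
       score_is_duplicate  coefficient_variation  score_break_length
label
False               0.796                  0.219               1.097
True                0.140                  0.072               0.951
```

Reading this: 40,000 mates yield 556 chimera candidates that collapse to
383 unique feature vectors. False candidates usually sit on ambiguous
(multi-location) anchors — `score_is_duplicate` near 0.8 — and have noisier
break support, while true junction breaks are clean (score_break_length
≈ 1, i.e. width ≈ k − 1, low support variation). Those three features are
the default modelling set.

The full study is one call (or `chimera-bench run --seed 0 --out report/`):

```python
from chimerabench import BenchmarkConfig, run_benchmark
result = run_benchmark(BenchmarkConfig(master_seed=1))
print(result.read_summary)    # ACC/Sens/Spec/Kappa/AUC per method and run
print(result.sweep)           # PPR/FDR per chimera-score threshold
```

On the default scaled-down conditions (five ~2 Mb genomes, 8 translocations
and 50k read pairs each) the final-run ensemble learners reach held-out AUC
≈ 0.995–0.996 with kappa ≈ 0.98, the KNN baseline on a single genome AUC
≈ 0.98, and event-level precision is 1.0 from threshold 0.7 upward — the
numbers `scripts/acceptance.py` recomputes.

A `chimera-bench` CLI exposes the stages individually (`make-ref`,
`mutate`, `simulate-reads`, `profile`, `train-reads`, `sweep`, `run`) for
running the pipeline on files, including user-supplied FASTA + GTF.

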