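# dmrscan

Genome-wide prediction of candidate differential DNA methylation regions
(DMRs, "epimutations") from genomic sequence features, using a sequential
machine-learning pipeline:

1. **Feature annotation** — each 1-kb genomic window is described by five
   feature subgroups (CpG information; repeat elements; transcription-factor
   consensus motifs; short DNA sequence motifs; mammalian PWM motifs),
   evaluated on the window itself and on 1 kb / 5 kb / 100 kb flanks both
   upstream and downstream (834 features in the standard catalog).
2. **Generalized-query active learning (GQAL)** — a tree-augmented naive
   Bayes (TAN) learner repeatedly picks its most uncertain unlabeled window,
   compresses it into a *generalized query* (the few most influential
   features with their value ranges), asks an oracle, and propagates a
   confident answer to every matching pool instance.  Features that keep
   appearing in queries (strictly more than 5 times) form the selected
   relevant-feature list.
3. **Imbalanced-class learning (ICL)** — AdaBoost.M1 over weighted TAN base
   learners: true DMR windows are rare, and re-weighting (rather than re-
   sampling) lets the committee learn both classes.
4. **Genome scan** — non-overlapping 1-kb tiling, per-window classification,
   and merging of runs of ≥ 3 consecutive positive windows into candidate
   DMRs (single positive windows are too noisy to report).
5. **Cluster (ECR) detection** — DMR counts in overlapping 2-Mb windows
   stepped every 50 kb, a one-sided Z-test against an empirical genome-wide
   null with Benjamini–Hochberg FDR, and merging of significant windows
   into multi-megabase candidate *epigenetic control regions*.

The intended users are computational epigenomics groups who have a modest
set of experimentally validated DMRs (e.g. from MeDIP-chip contrasts) and
want genome-wide candidate lists plus the genomic features that carry the
signal — typically CpG deserts (< 2 CpG/100 bp) with characteristic short
motifs such as CCGG, GCGC and TCGG.

## The core models

**TAN.** Attributes are discretized (equal-frequency bins); the attribute
tree is the maximum-weight spanning tree under class-conditional mutual
information I(Xi; Xj | Y) (Chow–Liu conditioned on the class); every
attribute also has the class as a parent.  Posteriors are

P(y | x) ∝ P(y) · Π_i P(x_i | x_pa(i), y),

with Laplace-smoothed, instance-weighted CPTs, so the same fitter serves
AdaBoost.

**AdaBoost.M1.** Round t fits a weighted TAN, measures weighted error ε_t,
sets α_t = ½·ln((1−ε_t)/ε_t), multiplies weights by exp(±α_t) and
renormalises; the committee predicts by the sign of Σ_t α_t h_t(x).

**Cluster Z-test.** For window count c against a genome-wide null with
location m and scale s, z = (c − m)/s and p is the upper normal tail; q
values are Benjamini–Hochberg.

Everything is seeded and deterministic; no downloads are required — a
first-class synthetic-data module (`dmrscan.simulate`) generates genomes,
repeat annotations, ground truth and simulated oracles reproducing the
study regime.

## Worked example (command line)

```bash
dmrscan simulate --seed 5 --out-dir sim --chromosomes 2 \
    --chrom-length 400000 --n-dmr-runs 8
# wrote synthetic genome (2 chromosomes, 8 planted DMR runs) to sim

# annotate a labeled training table with the library, then:
dmrscan train --features features.tsv --labels labels.tsv \
    --catalog catalog.tsv --rounds 5 --out model.json
# trained ensemble of 1 learners -> model.json

dmrscan scan --genome sim/genome.fa --repeats sim/repeats.out \
    --model model.json --catalog catalog.tsv \
    --out-sites sites.bed --out-dmrs dmrs.bed
# 800 windows scanned, 34 positive, 8 merged DMRs (min run 3)

dmrscan evaluate --dmrs dmrs.bed --genome sim/genome.fa \
    --repeats sim/repeats.out --catalog catalog.tsv --out report.tsv
# report written to report.tsv (max CpG density 0.80/100bp)

dmrscan cv --features features.tsv --labels labels.tsv --folds 5 --rounds 5
# ...
# mean  0.9800
```

Reading the numbers: the scan tiled the 0.8-Mb synthetic genome into 800
windows, called 34 positive, and merged them into 8 candidate DMRs — exactly
the 8 planted runs.  Every predicted DMR measures below 2 CpG/100 bp (max
0.80), i.e. the predictions sit in CpG deserts, and 5-fold cross-validation
of the boosted-TAN training reaches 98% accuracy on the held-out folds.

The same pipeline is available as library calls; see
`dmrscan.benchmarks.scan_benchmark` for a complete end-to-end run in ~15
lines.

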