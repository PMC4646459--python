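# Methods

This note records the models implemented in `dmrscan`, the parameter
choices that matter, what the synthetic benchmarks do and do not show, and
the numerical conventions.

## Coordinates and formats

All genomic intervals are 0-based half-open (BED convention).  FASTA is
read through pyfaidx and stored upper-case; assembly gaps (N) never match
any pattern and never count toward CpG statistics.  Repeat annotations use
the RepeatMasker `.out` tabular dialect (three header lines; 1-based
inclusive coordinates converted on input).  Models serialize to JSON
documents sufficient for bit-exact reload.

## Feature annotation

A window's feature vector is defined by an ordered catalog of
(name, subgroup, region, pattern) entries over seven regions: the base
window and 1 kb / 5 kb / 100 kb flanks on both sides.  Flanks are clipped
at chromosome ends; a fully clipped flank contributes 0 to every count
(and 0 density), keeping vector length fixed.

- *CpG information* (base window): length in bp, CpG count, CpG density
  per 100 bp.  CpG density of an empty sequence is an error upstream and
  0 under the clipped-flank rule.
- *Motif counts*: IUPAC consensus matching with overlapping occurrences
  counted (every start position tested) on both strands; a palindromic
  pattern is counted once per site.  Counts, not presence, are stored;
  presence is recoverable downstream by discretization.
- *PWM motifs*: log-odds scoring with pseudocount 0.01 against a uniform
  background; a position is a hit when its score reaches
  `min + f·(max − min)` of the attainable score range (default f = 0.8).
  Both strands, with the same palindrome rule.
- *Repeat elements*: the number of annotated intervals of the family
  overlapping the region by ≥ 1 bp (occurrence framing, consistent with
  the other subgroups).

The standard catalog has subgroup sizes 3 / 216 / 207 / 60 / 348 = 834.
Only a handful of motifs are fixed by the DMR literature (CCGG, GCGC,
TCGG); the remaining repeat families, TF consensi and PWMs are
reproducible placeholders generated from a fixed seed, because any
concrete 834-entry list is a configuration of the annotation run, not part
of the method.  Analyses that depend on feature *identity* therefore use
the compact signature catalog of the synthetic module.

## TAN

Discretization is per-feature equal-frequency binning fit on the training
matrix only (default 4 bins; constant features collapse to one bin;
out-of-range values clip to the end bins).  Structure is the maximum-
weight spanning tree under class-conditional mutual information, computed
in nats from weighted empirical frequencies; Kruskal with the fixed
tie-break (higher weight first, then lower index pair) makes the tree
reproducible, the root is attribute 0, and edges point away from the root.
Pairs involving a constant column have CMI 0.  Priors and CPTs use
additive smoothing 1.0; instance weights are normalised to total mass n so
the smoothing constant means the same thing at any weight scale (this
makes the fit exactly invariant to uniform weight rescaling).  Inference
runs in log space.

The bin count matters more than any other knob.  Equal-frequency edges
follow the *majority* of the data: with a 9% positive class, a 4-bin
split can leave every positive inside a bin shared with a fifth of the
negatives.  Rules of thumb used here and in the benchmarks: ~4 bins for
balanced tabular data; 2 bins (median split) for AdaBoost base learners,
which should be weak; 8+ bins when a rare class must be isolated along a
continuous feature such as CpG density (the first edge must fall inside
the rare class's mass, i.e. bins ≳ 1/positive-fraction).

## Generalized-query active learning

One iteration: (1) train TAN on the labeled set R; (2) pick the unlabeled
instance with posterior closest to 0.5 (ties to the lowest identifier);
(3) build the generalized query from the features with the largest
per-feature class log-likelihood-ratio magnitude at the instance's
observed bins — zero-influence features are don't-cares — up to the
feature budget, each retained feature constrained to its observed bin;
(4) the oracle answers with a label and a confidence; (5) if confidence ≥
the floor (default 0.6) every matching unlabeled instance takes the label
and moves to R, otherwise only the queried instance moves; (6) retrain and
evaluate on the monitoring set T1, stopping at the target accuracy or the
iteration cap.  The final model is scored once on the held-out set T2.
The discretizer is fit once on R ∪ U (labels are not used for binning) so
query ranges refer to stable bins.

The per-query feature tally increments each feature once per query it
appears in; features appearing strictly more than 5 times, plus manual
inclusions, form the selected list.

Two measurement conventions worth stating explicitly:

- *Oracle effort* is the number of generalized queries answered.  Labels
  propagated to matching instances cost the oracle nothing — that is the
  point of generalization — so the label-efficiency benchmark compares
  GQAL's query count against the number of individually labeled instances
  random sampling needs to reach the same held-out accuracy.
- *Query budget vs. task width*: a query over b features with k bins each
  matches a random instance with probability ~k^(−b).  With the default
  budget of 10 on a 50-feature task a query is effectively an instance
  description and propagation never fires; the benchmark uses budget 3,
  where a query matches tens of pool instances and generalization does
  real work.  The budget should scale with how coarse the informative
  structure is, not with the catalog size.

Uncertainty sampling alone is a poor strategy for a *generative*
classifier — boundary-only labels bias the class-conditional estimates —
which is visible in the benchmarks: the zero-propagation variant plateaus
below the passive curve, while bulk propagation restores broad coverage
of R.

## AdaBoost.M1

Two-class, weighting only (no resampling).  Uniform initial weights
summing to 1; α_t = ½·ln((1−ε_t)/ε_t); weights multiply by exp(±α_t) and
renormalise, which makes the just-fitted learner's error on the updated
weights exactly ½ (asserted to 1e-9 in tests).  A perfect round stops
boosting with ε floored at 1e-10 (α ≈ 11.5) to avoid infinite weights; a
round at ε ≥ 0.5 is discarded and boosting stops — if it is the very first
round the learner is kept with α = 0 and the ensemble is flagged
degenerate (it then always predicts the negative class, since exact-zero
margins resolve negative).  Discretization is fit once on the full
training matrix and shared across rounds so weight changes never reshuffle
bins.  Base learners default to 2 bins: a finely binned TAN reaches
near-zero weighted error immediately and leaves re-weighting nothing to
do, while median-split TANs are genuinely weak learners and express the
minority-recall benefit of boosting under 1:50 imbalance.

## Scan and merge

Non-overlapping tiles (default 1000 bp); a trailing partial tile is
dropped.  Classification streams in bounded chunks.  Merging requires
exact coordinate abutment on one chromosome and a minimum run of 3
windows; the merged record keeps the window count and mean vote margin.

## Cluster (ECR) detection

DMR membership in a 2-Mb window (stepped 50 kb) is by midpoint, so each
DMR counts at most once per window.  Windows are clipped at chromosome
ends rather than dropped.  The Z-test null is empirical and *robust*:
location = median, scale = 1.4826·MAD of per-window counts, estimated from
full-length windows only.  Two measured reasons: (i) genuine enrichment
contaminates plain moments — on the planted benchmark the global sd is
inflated ~2.7× by the clusters themselves, which masks them entirely;
(ii) clipped end windows have geometrically lower counts and drag the
centre down, which is anticonservative.  Plain mean/sd remain available
(`robust=False`).  p-values are upper normal tails (the count is treated
as approximately normal; its discreteness makes extreme tails slightly
optimistic), q-values Benjamini–Hochberg, significance q < 0.05.

Significant windows are grouped by overlap of their full extents, and the
reported cluster spans the *midpoints* of the grouped windows: a
multi-megabase window localises its evidence at its centre, and a union of
full extents would pad every cluster by up to a window length per side.
Cluster statistics are the count, mean span, and the fraction of all DMRs
whose midpoints fall inside clusters (flagged degenerate when there are no
clusters or no DMRs).

## Synthetic data

`SyntheticSpec` defaults encode the study conditions: five 2-Mb
chromosomes; background base composition A/C/G/T = 0.30/0.20/0.20/0.30,
giving an expected background CpG density of 100·p(C)·p(G) = 4.0 per
100 bp; 40 planted runs of 3–6 consecutive 1-kb windows separated by at
least one background window; a desert threshold of 2 CpG/100 bp; motifs
CCGG/GCGC/TCGG planted 3–8 times per positive window; one enriched repeat
family in the 1-kb flanks of each run over a scattered background of three
neutral families.  Planted windows are rewritten CG-free (every CG's G
becomes T) before motif planting, and any surplus CpGs from motif borders
are trimmed, so the measured density of every positive window is
*guaranteed* below the threshold.  All randomness flows from the single
spec seed through named `SeedSequence` children (sequence, placement,
planting, repeats).

Tabular benchmark tasks: the GQAL task has 5 informative features shifted
2.0 sd in the positive class plus 45 N(0,1) noise features, 2000-instance
pool (balanced); the imbalance task has 20 features shifted 0.6 sd at
~1:50 positives — a deliberately weak signal, the regime in which a single
classifier is imperfect and re-weighting has room to help; the chain task
gives binary attributes that copy their predecessor with probability 0.9,
the dependence structure that separates TAN from naive Bayes; the tree
sampler draws a random TAN generative model and exposes its exact
posterior as an oracle.

The simulated oracle answers a query with the majority truth label among
reference instances matching it, confidence = the majority fraction, with
optional seeded label noise.

**What the synthetic benchmarks do not show.**  Real methylation data has
sequence composition structure (isochores, CpG islands, repeat-driven
heterogeneity) that i.i.d. backgrounds lack; real DMR signatures are not
guaranteed-separable; real oracles (experts or assays) have structured
rather than independent noise; and real repeat annotations correlate with
sequence content.  Passing these suites demonstrates the machinery —
estimators, search, propagation, merging, calibration — not expected
field performance.  The full-genome scale of the original application
(2.6 M windows, tens of thousands of candidate sites) is supported by the
streaming scan but is not reproduced in tests, which run genomes of
0.8–50 Mb.

## Benchmark problem sizes

Structure search: 100 random CMI matrices on ≤ 5 attributes vs exhaustive
Prüfer enumeration.  Posterior accuracy: 5000 training samples per
generative model, averaged over 3 models (a single random tree can hold an
edge too weak to recover from finite data, which says nothing about the
estimator).  GQAL: 20 seeds, 60 iterations, 2000-instance pools, with a
10-labels-per-step passive arm.  Imbalance: 20 seeds at n = 5000.  Scan:
the default 5×2-Mb genome, training on 120 planted windows at 1:3 with
8 bins (the exact-recovery contract needs per-window recall near 1, not
the weak-learner regime).  Clusters: 200 DMRs on 5×10-Mb, 60%
concentrated in four 3-Mb regions; the null calibration repeats the
uniform layout over 20 seeds.
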