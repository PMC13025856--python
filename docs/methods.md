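# Methods

This note documents the models, conventions and numerical choices behind
`rloopscape`, and what the synthetic test bench does and does not show.

## Coordinates and formats

All coordinates are BED-style 0-based half-open, converted to 1-based only
at GTF emission. Chromosome names are matched exactly; readers expose an
opt-in `chr`-prefix normalisation (off by default — silent renaming hides
data errors). Strand is carried through the interval types but ignored by
all consensus/overlap arithmetic, because peak files give no reliable
strand for R-loops; the same reasoning makes every sequence statistic
strand-agnostic (absolute skews, both-strand motif scans).

## Consensus ("common") region calling

1. **Base partition.** All datasets' peaks are flattened per dataset
   (within-dataset overlaps merged — coverage is boolean) and the genome is
   cut at every peak boundary, producing disjoint segments each labelled
   with the exact set of covering datasets (bedtools `multiinter`
   semantics).
2. **Group rule.** A segment is kept when every required method group
   contributes ≥ `min_datasets_per_group` covering datasets (default 1;
   the default required groups are all groups present).
3. **Span recovery.** Intersections shrink peaks, so each kept segment is
   expanded to the full coordinates of *every* peak (any dataset)
   overlapping it. Collecting from all datasets rather than one per group
   is deliberate: span recovery is dataset-agnostic, and the union is what
   merging operates on anyway.
4. **Merge.** The collected spans are merged with `merge_gap` (default 0,
   which also joins book-ended intervals — the bedtools `merge` default).
   Segments that were distinct before span recovery may coalesce; the
   merge is the final arbiter.

Provenance (contributing dataset ids per output region) is recorded.
Equivalence with a per-base brute-force implementation is asserted over
500 randomized instances in the test suite.

## Annotation

One category per region, decided by the region midpoint against
priority-ordered element sets: promoter-TSS > 5'UTR > 3'UTR > exon > TTS >
intron > intergenic. The promoter window is (−1000, +100) around the TSS
in gene orientation; the TTS window is ±1000 bp; both configurable — a
ChIPseeker-style broad-promoter annotation is the same annotator with
promoter_window = (3000, 3000). CpG-island overlap is a separate boolean
column, not a category: CpG islands are not gene features. Signed TSS
distances are negative upstream in gene orientation; equidistant TSS ties
break to the lexicographically smaller gene id, making annotation fully
deterministic. Feature enrichment compares observed category fractions
with the genomic share of each category computed from the *same* priority
partition, so both fraction vectors sum to 1 and a uniform region
generator gives log2 ratios near 0 (asserted at 50,000 regions, |log2| <
0.1).

## Expression

CPM = count / library size × 1e6; the expressed-gene universe is CPM ≥ 1
in ≥ 1 sample (inclusive boundary). TMM normalization follows Robinson &
Oshlack: reference sample = upper-quartile CPM closest to the mean upper
quartile; M/A computed on doubly-positive genes; two-sided trims of 30 %
(M) and 5 % (A); precision weights from the binomial delta method; factors
scaled to geometric mean 1 (asserted to 1e-9). Mean expression is
summarised as mean log10(TMM-CPM + 1), CV as sd/mean on the linear scale
— the two scales are deliberately different (the log scale stabilises the
mean display; a log-scale CV would compress exactly the variability the
statistic is meant to show) and both are configurable.

A gene is *associated* with the consensus set when it is the nearest-TSS
gene of ≥ 1 region at |distance| ≤ 3 kb. The ±3 kb default is the broad
promoter convention; a nearest-gene-only rule (no window) is available by
passing an effectively infinite distance.

## Chromatin states and windows

Fold enrichment per state is (C/A)/(B/D). Windows: maximal runs of
book-ended same-state segments are tiled left-to-right with L = 200 bp
windows; the trailing remainder < L is discarded rather than padded, so
every window supports like-for-like skew/G4 comparisons. `f = 0.5` is the
default R-loop window rule (overlap ≥ f·L, inclusive); `"any"` (≥ 1 bp)
reproduces an unthresholded intersect. Classification is monotone in f by
construction. The fraction of consensus bp captured by R-loop windows is
reported as the coverage diagnostic used when choosing f. Windows with
> 50 % N bases are dropped during featurization (assembly-gap behaviour);
the drop count is reported.

## Sequence features

- Skews: |(G−C)/(G+C)| and |(A−T)/(A+T)| with N excluded from counts and
  a 0 convention for empty denominators.
- Quadparser: regex `G{3,}([ACGTN]{1,7}G{3,}){3}` counted left-to-right,
  greedy, non-overlapping, plus the C-run mirror for the reverse strand;
  the two counts are summed.
- G4Hunter: per-base scores ±min(run length, 4) in G/C runs, 0 elsewhere;
  sliding means over a 25-bp window (the published default; the window is
  configurable because sources differ); a hit is a maximal run of
  consecutive windows with |mean| ≥ 1.2. Window sums use exact integer
  arithmetic so threshold comparisons have no float fuzz. Sequences
  shorter than the window get one whole-sequence mean. Both the maximum
  |score| and the merged hit count are emitted, since either summary may
  be wanted per window.
- IUPAC motifs: overlapping occurrences all count (lookahead matching),
  both strands; sequence N matches only motif class N.
- `external_score`: any per-window numeric predictor (e.g. a trained
  G4-propensity model) can be attached by file, so motif counts, structure
  scores and skew are comparable on one footing without bundling a model.

## Statistics

**Permutation subsampling.** Null means are generated by drawing
|input| background values *without replacement* n_perm times (default
10,000); with-replacement sampling is used, and flagged, only when the
pool is smaller than the input. The empirical p is the plain proportion of
null means ≥ observed — no +1 smoothing, exactly as the subsampling
scheme defines it; the 1/n_perm floor is attached as metadata so p = 0 is
interpretable. An exhaustive mode enumerates every subset (used by tests
on pools ≤ 12). Caveat stated plainly: the null variance carries a finite-
population correction, so p is uniform under the iid null only when the
pool is large relative to the input — the regime the pipeline operates in
(hundreds to thousands of ex-R-loop windows per state). Tests assert
decile uniformity (10 % ± 3 %) at input 10 vs pool 500. BH q-values are
added per feature family across states; the raw empirical p is always
reported alongside.

**Motif enrichment.** Hypergeometric upper tail on the combined
target+background sequence universe (binomial alternative available), BH
across the motif × state family. No GC-matched background autonormal-
ization is attempted; the ex-R-loop windows of the same state are already
the composition-matched background.

**ORA.** Hypergeometric upper tail per term after intersecting terms with
the expressed-gene universe; BH over tested terms; significant iff
p < 0.01 and q < 0.05 jointly.

**Permutation importance.** Stratified 5-fold CV, a fresh 500-tree random
forest per fold (any `fit`/`predict_proba` estimator can be plugged in),
each feature shuffled in the held-out fold 10 times; importance = mean
decrease from the fold's baseline AUC. Run on a class-balanced sample
(all R-loop windows + an equal random draw of background windows) so AUC
decreases are comparable across runs.

## Synthetic data

The generator emulates the full input suite with known truth. Defaults —
chosen once as the reference conditions — are: 2 chromosomes × 2 Mb; six
chromatin states (TSS, PromF, Tx, TxEx, EnhA, Quies) from a first-order
chain with geometric segment lengths and state-specific GC content
(0.60/0.55/0.45/0.50/0.50/0.40); 500 true loci (lognormal lengths, median
≈ 150 bp, ≥ 4 kb apart) with planted |GC skew| 0.4 (G-tilted composition
at the state's GC level), planted canonical G4 motifs at 1/kb, and a
degenerate motif planted at rate 0.8 in Tx/TSS loci with an unplanted
control motif; 13 peak datasets (DRIP ×4, CUT&Tag ×3, HBD ×3, MapR ×3)
with per-locus detection sensitivity 0.9, Gaussian boundary jitter
(sd 20 bp, detections clamped to keep ≥ 1 bp on their locus), and uniform
noise at 5 peaks/Mb; 1,000 non-overlapping genes of 1–2.5 kb, 250 of them
"associated" with their TSS within 1 kb of a locus midpoint; negative-
binomial counts over 6 samples (means 300 vs 60, dispersions 0.05 vs 0.4,
library sizes 0.8–1.2 M) and 10 gene sets of 50, one drawn 80 % from
associated genes. With 3–4 datasets per group at sensitivity 0.9, the
chance a group misses a locus is ≤ 0.1³, so consensus recovery ≥ 99 % is
expected and ≥ 90 % is asserted across seeds.

What the bench does *not* emulate: read-level noise and peak-caller
artefacts, mappability and blacklist structure, realistic state
transition grammar, correlated replicate noise, isoform structure, or
mm10-scale genome composition. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration of the pipeline, not
biological re-discovery on real data. Gene count and length deviate from a
naive desk-scale reading (non-overlapping realistic gene bodies cannot be
packed 2,000-fold into 4 Mb); loci are placed state-agnostically by
default, so state fold enrichments hover near 1 unless state-biased
placement is switched on — which is exactly what the calibration tests
need.

## Problem sizes and determinism

Tests and the acceptance script run the generator at its default scale
(full pipeline in well under a minute per run; the whole suite in a few
minutes), with n_perm reduced where only reproducibility rather than
p-resolution is being asserted. Every stochastic routine takes a seed or
Generator; the simulator spawns one child stream per stage so adding a
stage never perturbs another's draws; the pipeline manifest records a
config hash (output directory excluded) and a content hash per output
file, and identical configs reproduce identical hashes bit for bit.

## Known limitations

- The consensus caller is peak-based; it cannot weigh signal strength, so
  a weak-but-consistent region and a strong one are equals (IDR-style
  modelling is out of scope).
- The permutation null conditions on the observed window classification;
  it does not re-draw region placement.
- HOMER-style de-novo motif discovery, GO semantic clustering, and
  trained G4 structure predictors are intentionally not reimplemented;
  the external-score hook and the known-motif scanner are their interface
  points.
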