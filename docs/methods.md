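# Methods

## Coordinates and overlap

All intervals are 0-based half-open (BED convention); readers for 1-based
formats must convert on input. Two intervals overlap iff they share at
least one base pair — no minimum overlap fraction is applied anywhere.
Chromosome names are matched verbatim. The promoter window of a gene is
the symmetric interval `[tss − flank, tss + flank + 1)` around the
strand-aware TSS (default flank 1 kb), so a region at distance exactly
`flank` still overlaps it; "within 1 kb" is read as two-sided because
nothing in the definition distinguishes upstream from downstream.

The overlap engine keeps, per chromosome, start-sorted arrays with a
running maximum of ends (vectorised any-overlap queries in O(log n)) and a
lazily built interval tree for overlap *listing*. Both paths are contracted
to the brute-force nested-loop answer and tested against it.

## Classification cascade

The four CGI classes are assigned in a fixed priority order: promoter
status (overlap with any coding-gene promoter window) trumps activity
(overlap with ≥1 H3K27ac **and** ≥1 DHS peak), and activity trumps
transcript evidence (overlap with a CAGE TSS or a de-novo transcript
promoter window). Only protein-coding genes define `pCGI`s; noncoding
annotated genes are deliberately excluded from the promoter rule, matching
the accession-prefix convention for coding transcripts. De-novo transcript
TSSs get the same ±1 kb window as annotated genes; CAGE TSS intervals are
used as supplied. Typical enhancers are anchored on the DHS peak
coordinates with H3K27ac as a required overlapping mark, then filtered
against all CGIs and all TSS evidence.

## Signal profiles

A region's center is `floor((start+end)/2)` (even-length regions have no
true center; flooring is normative). Metaprofiles split `[center − flank,
center + flank)` into `n_bins` equal bins (defaults 5 kb / 200 bins = 50 bp
bins, matching the visual resolution of the published profiles) and take
the bp-weighted mean of piecewise-constant bedGraph coverage per bin;
uncovered bases count as zero. Bins are averaged across regions; a bin
lying entirely before the chromosome start is undefined for that region
and excluded from the cross-region mean, and a bin straddling position 0
averages over its defined part only. Raw coverage is profiled — no
peak-normalisation — since nothing specifies otherwise. Condition
contrasts at fixed regions use per-region bp-weighted means and a paired
Wilcoxon signed-rank test on tumor − normal differences.

## Rank tests

Small samples get exact permutation nulls: the rank-sum test enumerates all
C(n+m, n) rank assignments when both samples have ≤ 10 observations, and
the signed-rank test computes the exact distribution of W⁺ over all 2ⁿ
sign assignments by generating-function convolution for n ≤ 25. Both use
midranks, so ties are exact; doubled ranks keep the arithmetic integral.
Larger samples use the tie-corrected normal approximation with continuity
correction (checked against scipy's asymptotic forms). Zero differences
are dropped; an all-zero input is reported as degenerate with p = 1.

The eCGI-vs-typical-enhancer interaction-strength comparison uses the
two-sample rank-sum form even though the source analysis names the
signed-rank test: the two pair sets are unpaired and generally of unequal
size, so a paired statistic is not applicable. A paired variant remains
available behind `paired=True` for equal-length samples.

## Permutation enrichment

The observed statistic is the number of *distinct* regulator genes
targeted by the query regions through filtered links (matching the
"number of transcription regulators" axis of the published histograms,
rather than link counts; a link-count mode is not provided since distinct
genes is the quantity reported). Each permutation replaces the regions
with random segments that preserve count, length and chromosome; length
and chromosome matching is a normative strengthening of "the same number
of random DNA segments" that keeps the null comparable, and can be turned
off (`match_length=False` falls back to count-only matching with the
median template length). Placement is uniform with rejection against an
optional exclusion list (error after 10⁴ rejections). The empirical
p-value uses add-one smoothing, p = (1 + #{null ≥ obs})/(1 + N), so p ≥
1/(N+1) and results are bit-reproducible given (seed, N).

Because promoter-side overlaps never change across permutations, the
permutation loop precomputes (link anchor → regulator gene) hits once and
re-evaluates only the vectorised region-overlap flags per permutation;
a test pins this fast path to the plain `assign_targets`-based count.

Calibration is checked on a null genome in which the query regions are
themselves uniform random segments (one 5 Mb chromosome, 400 genes, 1500
links, 150 query segments, half the genes labelled regulators): p-values
over 500 independent datasets are compared to U(0,1) by a KS test. The
null-genome dimensions were chosen once so that the discrete
distinct-gene count spreads over enough values for the uniformity check to
be informative.

## Fisher enrichment

Two-sided Fisher exact p (sum of hypergeometric point probabilities not
exceeding the observed table's) is delegated to scipy; an exhaustive test
verifies it against an independent hypergeometric enumeration for every
2×2 table with total ≤ 60. The reported odds ratio is the sample odds
ratio (a·d)/(b·c), with 0/0 → NaN and x/0 → ∞.

## Methylation

dm = β_tumor − β_normal per CpG, computed only over positions present
with a valid beta in both conditions (dropped rows are counted and
logged); betas outside [0, 1] are an error naming the position. A region's
methylation change is the **mean** dm over contained CpGs — the robust
reading of "a > 0.5 methylation increase", since single-CpG excursions
should not flip a region; an any-CpG mode exists behind `mode="any"`.
Selection is strictly greater than the threshold (0.5 for cell-line
contrasts, 0.1 for clinical), and the selected-set nesting in the
threshold is property-tested. Group-mean betas per condition are assumed
upstream (one value per CpG, 450K-style, strand-collapsed). Target
silencing computes (expr_tumor + pc)/(expr_normal + pc) per target gene of
the hypermethylated regions (pseudocount 0.1 RPKM; none is prescribed, so
a conventional small constant is used), tests log-folds < 0 by the
one-sample signed-rank test, and contrasts against targets of
non-hypermethylated regions by rank-sum. When interaction data are absent
the nearest gene by TSS-to-midpoint distance substitutes for ChIA
evidence (ties break to the smaller TSS coordinate, then gene id).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: a
toy genome (3 × 10 Mb) laid out on a 20 kb slot grid with one planted
entity per slot, so no element contaminates another's promoter window or
peak overlap and the planted labels are exactly identifiable at zero
noise. Class counts follow the configured mix by largest-remainder
apportionment. pCGIs sit on coding-gene promoters and carry peaks and CAGE
evidence (promoters are active; the cascade's priority rule absorbs
this); npCGIs carry both peaks plus a CAGE TSS; eCGIs carry both peaks and
no TSS evidence; inactive orphans lack at least one peak. eCGIs loop to
1–3 same-chromosome gene promoters with a 3× preference for regulator
genes and tag counts 3 + shift + Poisson noise; typical enhancers loop
without preference at baseline tag counts; sub-threshold noise links
(tags 1–2) exercise the filter. Hypermethylated eCGIs add dm 0.6 with
Gaussian CpG noise (sd 0.05, clipped to [0, 1]); their targets' expression
is divided by the silencing fold (3×) under log-normal noise (sd 0.3 in
log2, the conventional abundance model); tumor coverage at those islands
is halved. CpGs are placed 25 per CGI; background CpGs are drawn at one
per 2 kb — dense enough to exercise the matching and aggregation logic
without dominating runtime at desk scale. Peak dropout draws from a
dedicated RNG stream with unconditional draws, so the dropped-eCGI sets
are nested as the dropout probability grows and recall is exactly
monotone; the rest of the dataset is byte-identical across dropout
settings.

What the generator does **not** emulate: realistic sequence composition
(sequence statistics are computed only when sequences are supplied),
overlapping or nested genes, peak-width and signal-shape heterogeneity,
inter-chromosomal loops, array measurement error structure, or biological
covariation between layers beyond the planted effects. Passing tests
therefore demonstrate correctness of the *computations* under the planted
model, not performance on real epigenomes.

## Problem sizes and determinism

Default study conditions: 600 CGIs / 400 genes for the worked analysis;
1000 CGIs with 300 eCGIs and 30 planted hypermethylated islands for
recovery checks (90 when ≥100 distinct silenced targets are needed, since
targets are shared between islands); 1000 permutations for enrichment;
200-replicate power grids and a 500-dataset calibration study for the
statistical machinery. Every random step is driven by an explicit seed
through `numpy.random.default_rng`; reports are serialized with sorted
keys so identical (inputs, config, seed) produce byte-identical output.

## Known limitations

* The classification takes the CGI catalogue as input and never calls CGIs
  from sequence.
* Coverage handling is bedGraph-based piecewise-constant signal; no
  read-level pileup or input normalisation.
* The permutation null does not exclude gaps/blacklist regions unless an
  exclusion list is supplied.
* The clinical-threshold (0.1) path shares all machinery with the
  cell-line path; no sample-pairing model for heterogeneous clinical
  cohorts is implemented beyond group-mean betas.
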