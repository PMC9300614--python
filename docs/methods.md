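# Methods

## Scope and data model

All coordinates are 0-based half-open (BED convention); GTF-style 1-based
input must be converted at the boundary. Chromosome names are compared as
exact strings, with a warning listing names present in only one input.
Counts are cell-by-feature sparse matrices in Matrix Market triples with
barcode and feature index files; a peak's counts are attributed to the
peak's interval, and a peak "maps within" a window iff it overlaps it by at
least 1 bp — counts-level data cannot localise fragments inside a peak, so
no proportional splitting is attempted.

## Barcode QC

Tukey far-out fences `[Q1 − k·IQR, Q3 + k·IQR]`, `k = 3`, are computed once
per metric on the full input (never iteratively) with linear-interpolation
("type 7") quartiles; the discontinuous quantile variants are selectable
because the convention is not universal. A barcode is removed iff any
listed metric is strictly outside its fences; fence-boundary values are
kept. The fixed-range filter keeps barcodes with log10 total counts in
[3, 6] and promoter ratio in [0.05, 0.6], both closed. The default
simulation produces per-cell totals of order 10², chosen so that metacell
binarisation stays informative (below), so the range filter's literal
bounds are exercised on constructed tables rather than on the simulation.

## Scoring

The promoter window is the 2 kb strand-aware stretch upstream of the TSS:
`[tss−2000, tss)` on plus-strand genes, `[tss, tss+2000)` on minus-strand
genes, clamped at the chromosome start. PA sums counts over
window-overlapping peaks; a peak overlapping two genes' windows counts for
both. GAS sums over the union of peaks overlapping the promoter window,
the first exon, and any enhancers assigned to the gene — union semantics,
so a peak spanning two components contributes once. Whether the original
procedure counted such peaks once or per component is not documented;
union was chosen as the conservative reading and is pinned by a
brute-force membership oracle in the tests. A promoter-plus-gene-body PA
variant is exposed as `mode="gene-body-plus-promoter"`. Each gene carries
one transcript model (one first exon); multi-transcript genes are out of
scope.

## Differential accessibility

The per-peak test is a logistic likelihood-ratio test of the in-cluster
indicator on the log1p median-depth-normalised signal, conditioning on log
total counts; the statistic is twice the log-likelihood difference against
the depth-only null, referred to χ² with 1 df. Peaks are tested when
max(pct_in, pct_out) ≥ 0.2. Fits use a dedicated damped-Newton solver
(step-halving, monotone ascent). Separated or non-convergent fits are
refit with an L2 penalty of 1e-4 on all slope coefficients of both models
and flagged; the penalty keeps the statistic finite and the behaviour
deterministic on degenerate peaks. Multiple testing uses Benjamini–
Hochberg within each cluster — the source procedure names an FDR
criterion while its implementation's default is Bonferroni; the stated
criterion is implemented. Calls require adjusted p ≤ 0.05 and positive
average log fold change (difference of mean log1p-normalised signal).

The overlap matrix uses pooled-per-cluster semantics: a DA peak of cluster
c "overlaps" cluster d iff the summed count over d's cells is positive, no
minimum threshold. Whether the original quantity pooled reads per cluster
is not fully explicit; pooling is the plain reading of "reads in a peak in
another cluster". Profile clustering is average-linkage (UPGMA) on
1 − Pearson distance between overlap rows; zero-variance rows are assigned
the maximal distance 2 to keep the matrix complete and the tree
deterministic.

## Co-accessibility and TSS–cRE links

The estimator is a declared stand-in for the published graphical-lasso
tool, whose internals are out of scope: cells are pooled into metacells of
50 by pseudotime order within (region, state) (remainders merged into the
last metacell), pooled counts are binarised at > 0, and the score of a
same-chromosome pair within 0.5 Mb is the Pearson correlation of the
binarised profiles. Constant profiles are excluded. Externally computed
link tables are accepted wherever links are consumed, so the filtering and
classification logic can post-process real estimator output. Links are
kept at score ≥ 0.25 (inclusive; the source alternates between "equal to
or greater" and "greater than", and inclusive was chosen and made
configurable). A TSS–cRE connection requires exactly one anchor to overlap
a TSS point (slop 0 by default: peaks containing the TSS are the promoter
peaks) and the other anchor to overlap no gene's promoter window.
Per-group link counting downsamples every group to the smallest group's
size without replacement and re-runs the estimator per group — the
conservative reading, rather than subsetting precomputed links. The
gene–peak model fits `P(peak count > 0) ~ 1 + normalised expression` per
(gene, peak) for genes whose TSS-overlapping peak has nonzero total count
and peaks within ±250 kb of the TSS (a 0.5 Mb window centred on the TSS),
with genome-wide BH and retention at FDR ≤ 0.05.

## Enhancer integration

Scores per route (co-accessibility scores; −log10 adjusted p for the
model, with infinities replaced by 2× the greatest finite value over the
whole table — the cap is global, not per gene, following the singular
"greatest value"; the alternative normalisation-ceiling reading is noted
but not implemented) are percentile-ranked per gene with average ties.
TSS-overlapping peaks are excluded, intervals are extended 500 bp both
ways, clamped at zero and merged; bookended intervals join, since at the
±500 bp scale adjacency is equivalent to overlap. Union mode concatenates
and re-merges (provenance per contributing route); intersect mode takes
base-pair intersections with provenance "both" — the stringent list.
Ranks are carried through by interval overlap and no rank cutoff is
applied (none is documented); an optional minimum-rank filter defaults to
off. The H3K27ac filter keeps candidates overlapping the union of the
provided H3K27ac sets by ≥ 1 bp. Overlap reports state the percentage of
A-intervals hitting B; the Venn core count is the minimum of the two
per-side hit counts so it never exceeds either set size.

## Trend analysis

Pseudotime is an input (graph-based pseudotime inference is out of scope);
cells are split into 10 equal-width bins, left-closed with the last right
edge inclusive. Per gene and modality, bin means are centred and scaled
across bins using the sample standard deviation (ddof = 1, matching R's
`scale()`; the population variant is available via `ddof=0`). Constant
trajectories become all-zero and are flagged; empty bins are linearly
interpolated and flagged so the contract is total. Genes are clustered on
the concatenated RNA/GAS/enhancer z-vectors with correlation distance and
average linkage; the cut k maximises mean silhouette over k ∈ 2..8 with a
deterministic smallest-k tie-break — the reference tool's undocumented
cutting heuristics are replaced by this documented, deterministic
substitute filling the same analytic role. Joint concatenation (rather
than per-modality clustering with reconciliation) matches the matched-
heatmap construction; a per-modality mode exists but is unvalidated.
Groups below 6 genes fall into "other"; retained groups are labelled early
or late when the group's modality-averaged mean z falls or rises by more
than 0.5 from first to last bin, otherwise transition. DEGs between
maturation states reuse the logistic LR test on expression (one-vs-one,
depth covariate, BH per transition) with an absolute log-fold-change
prefilter of 0.1: under a global shift in expressed-gene content,
depth normalisation inflates unchanged genes' normalised means
(compositional artifact), and the prefilter—standard in the field's
marker-detection tools—suppresses those spurious calls. Transition counts
tally distinct enhancers linked to ≥ 1 up- (activated) or down-regulated
(decommissioned) gene; an enhancer linked to both counts in both tallies;
an all-zero denominator yields a flagged infinite ratio.

## Synthetic data generator

The generator emulates the study conditions at desk scale: 4 regions × 3
states × 150 cells (1800 cells), 200 genes, ~1200 peaks, minutes on one
CPU. Each gene receives a scope (pan-regional with probability 0.2,
otherwise one region with CTX weighted ~0.61 among region-scoped genes so
that one tissue carries a denser regulatory program, as in the data the
design mirrors) and a temporal class: early (on from pseudotime 0, off at
τ_off — 90% in (2.0, 2.4), 10% in (0.6, 1.0)), late (on from τ_on ∈
(1.2, 1.8)), or, for region-scoped genes only, constitutive. Pseudotime is
state rank plus uniform jitter on [0, 1), so activity thresholds are
continuous: loci switch smoothly rather than at state boundaries. The τ
distributions plant progressive repression — activation concentrates at
the AP→BP boundary while decommissioning concentrates in BP→N — which is
what the transition-ratio analysis is expected to recover.

Counts are Poisson given a log-normal per-cell depth (σ = 0.4): active
elements at rate 0.5 per cell, inactive at 4e-4 (a gamma-Poisson
dispersion hook exists but defaults off — the rank/threshold statistics
under test do not require overdispersion). Accessibility uses the
expression window with the onset shifted one maturation state earlier
(`rna_lag = 1`), so chromatin opens before transcripts rise. Promoter
peaks additionally keep a constitutive floor of 5% of the active rate and
close half a state later than the gene's other elements: promoter openness
is partially activity-independent and decommissioning is enhancer-led.
This is also what makes the full GAS a better correlate of expression than
a promoter-only score. Each gene has one promoter peak (its promoter
window), one first-exon peak, 1–3 enhancers and 2 local background peaks
on a 10 kb offset grid within ±95 kb of the TSS; genes sit 600 kb apart so
that neighbouring genes' elements fall outside the 0.5 Mb pairing window —
at the fixed scale of 36 metacells, binarised correlations are too noisy
to separate same-program neighbours reliably, so the geometry, not the
statistic, provides the isolation. Outlier barcodes (5%) are re-drawn with
their ATAC depth scaled to land at twice the Tukey far-out upper fence of
the remaining cells' totals, i.e. they are outliers by construction.
Histone sets per region place H3K4me3 at promoters of regionally active
genes, H3K27me3 at promoters of inactive genes, and H3K27ac at true
enhancers of active genes with a 10% false-negative rate.

What the generator does not emulate: doublets, batch effects, read-level
fragment structure, negative-binomial overdispersion (by default),
trans-chromosomal or promoter–promoter regulation, and realistic
sequencing depths (totals are ~10² per cell rather than 10³–10⁴). Passing
recovery tests therefore demonstrates the correctness and calibration of
the implementations under the planted model, not their performance on real
tissue.

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds (numpy Generator);
identical (design, seed) reproduce byte-identical outputs, and the CLI
writes with fixed float formatting to keep reruns binary-equal. Logistic
fits are monotone damped-Newton with a 1e-9 step tolerance and at most 60
iterations. Hierarchical clustering uses scipy's average linkage on
condensed 1 − r matrices; leaf order is scipy's deterministic ordering of
the input. Problem sizes in the test suite and acceptance script (the
default 1800-cell simulation, 10 seeds for recovery averages, 2000 null
features for calibration, three seeds for the differential-accessibility
tally) were chosen so the whole validation runs in a few minutes on a
single CPU while keeping Monte-Carlo margins comfortable.
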