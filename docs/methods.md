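# Methods

## Coordinate conventions and interval algebra

All internal coordinates are 0-based half-open `[start, end)`; GFF3
(1-based closed) is converted on read and write. Overlap is strand-blind
everywhere and a single shared base counts as overlap (`min_overlap_bp=1`),
the convention used for every gain/loss, transientness and enrichment call.
Promoter and downstream assignment windows are strand-aware. Interval
merge/subtract/overlap are direct sorted sweeps; the test suite pins them to
quadratic brute-force scans on hundreds of random instances.

### Peak-to-gene assignment

A peak is assigned to a gene when it overlaps one of the gene's candidate
windows: promoter (`up_bp=3000` before the TSS), exon, intron, 5'UTR, 3'UTR,
or downstream (`down_bp=2500` beyond the TES). When several windows (of one
or several genes) overlap the peak, position priority decides
(promoter > exon > intron > 5'UTR > 3'UTR > downstream); ties at equal
priority fall back to the smallest peak-midpoint-to-TSS distance, then to
lexicographic gene id. The distance/lexicographic tie-break is this
package's choice — the nearest-gene principle alone does not define ties.
Peaks touching nothing are distal. For the three-way ACR taxonomy,
promoter assignments become pACRs, genic assignments (exon/intron/UTRs)
gACRs, and everything else — including downstream-window assignments —
dACRs, so the taxonomy is a strict partition; the pACR window equals the
annotation window.

### Shuffled backgrounds

`shuffle_intervals` places each query interval independently and uniformly
over all feasible start positions in a (merged) background domain;
overlaps among placed intervals are allowed, matching the behaviour of the
standard genome-arithmetic shuffle. Enrichment reports
`observed / mean(expected)` over `n_shuffles` placements (default 100;
the pipeline uses 50) and a Fisher exact p-value (greater) that pools all
shuffles into a single 2×2 table — the pooling layout is this package's
choice. Degenerate expectations are flagged (`inf` when observed > 0 with
zero expectation, `nan` for 0/0) rather than silently dropped.

## Statistical primitives

* **Fisher exact**: the first cell is hypergeometric given the margins;
  the two-sided p sums all table probabilities at most the observed one
  (relative tie tolerance 1e-7). Enrichment-style calls use
  `alternative="greater"`; overlap-significance calls are two-sided.
* **Mann–Whitney U**: exact when n1+n2 ≤ 12 without ties, via the
  rank-sum count recurrence; otherwise a normal approximation with tie and
  continuity corrections.
* **Pearson**: t-based p with n−2 degrees of freedom; zero-variance input
  returns a result flagged `undefined` with p=1 so screening consumers drop
  the pair instead of crashing.
* **FDR**: Benjamini–Hochberg step-up (the procedure choice is
  configurable at the call sites that consume it).
* **Differential calls**: a Welch t-test on log2(x+1) replicate values
  with BH FDR; a gene is Up/Dn at |log2FC| ≥ 1 and FDR ≤ 0.05. This is a
  deliberate lightweight stand-in for a count-model DEG engine, which is
  out of scope; the thresholds and direction conventions are unchanged.

## Pseudotime and angular ordering

Stage samples (per-gene z-scored stage means) are projected by PCA; the
developmental time unit (DTU) of stage *i* is the cumulative Euclidean
distance between consecutive stages in the first two PCs, rescaled so the
path spans [0, 10]. Per-gene profiles are smoothed by a tricube-weighted
local quadratic regression (span 0.75, ≥ span·n neighbours per fit)
evaluated on 500 uniform DTU grid points; the smoother is linear in the
responses, so one hat matrix serves all genes. Gene ordering runs PCA over
genes (observations = per-gene z-scored 8-sample profiles; a flag switches
to the 500-point curves) and ranks by atan2(PC2, PC1). Two gauge freedoms
are fixed deterministically: rank 0 goes to the gene whose smoothed curve
peaks earliest in DTU, and the direction of travel is the one for which
peak time increases with rank. PCA signs follow a largest-loading-positive
convention so reruns are bitwise stable.

## Regulatory-network inference

Candidate edges arise from motif hits (supplied as intervals with a
motif→TF map; scanning/footprinting is not reimplemented) that fall inside
ACRs carrying a gene assignment. Motifs are screened per cluster of ACRs by
Fisher (greater) against background ACRs at p < 0.05. A candidate
(TF, target) survives when the Pearson test between the two stage-mean
profiles gives p < 0.05 and, by default, r > 0 — the positive-sign filter
reflects the synchronous TF/target patterns the method is meant to capture
and can be disabled. Duplicate (TF, target) pairs keep the smallest p.
Family collapsing produces module-level edges weighted by member-edge
count; the TF–TF subnetwork restricts targets to TFs and attaches each
node's first activation stage (first stage with z ≥ 1).

## Polyploid triad bias and divergence

Triad A/B/D expression fractions are classified to the nearest of seven
simplex centroids: balanced (⅓,⅓,⅓), X-dominant (unit vectors), and
X-suppressed ((0,½,½) and permutations); exact ties resolve to balanced. A
triad is "expressed" when its member-mean TPM reaches 0.5. Divergence
between a hexaploid gene and its ancestor counterpart is the Pearson r of
their stage profiles; genes are clustered on r by deterministic 1-D k-means
(centers seeded at min/median/max, labels ordered by cluster mean into
dysfunction < middle < conserved; degenerate data with fewer distinct
clusters keeps the extreme labels first). A fixed-threshold mode is
available for strict reproducibility. TE-in-promoter enrichment tests TE
presence in the strand-aware window [TSS−3000, TSS−1500) by Fisher
(greater).

## Synchronization and mark contribution

A gene's RNA and promoter-accessibility profiles are z-scored over stage
means; the activation stage is the first stage after baseline where z ≥ 1.
A gene counts as synchronized when both modalities activate, the lag is at
most one stage, and the profile correlation is ≥ 0.8; all three thresholds
are parameters, because the underlying notion is not standardized.
"Contribution" of a chromatin mark to expression at a stage is
operationalized as the squared Pearson correlation across genes between
promoter mark signal and log2(TPM+1) at that stage — r² treats activating
and repressive marks symmetrically; the definition is recorded in the
output metadata.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions every recovery test runs under.

**Genome.** Three 2-Mb chromosomes (subgenomes A/B/D) carry 500 collinear
triads plus 100 singletons in identical slot order, with two-exon gene
models and UTRs. Intergenic gaps are a mixture of short (0.2–0.6 kb) and
wide (6.5–11.5 kb) gaps; wide gaps provide the gene-distal space (> 3 kb
from any gene span) needed for distal peaks. TEs fill 40% of intergenic
bases in chunks. Per-gene divergence labels (conserved 62% / middle 30% /
dysfunction 8%) are drawn up front; dysfunction genes preferentially (70%
vs 10%) receive a TE planted 1.5–3 kb upstream of the TSS on the 5' side
of the gene, which forces a wide 5' gap.

**Expression.** Each transcription unit follows a stage-specific pulse —
logistic rise (width 0.7 stages) at its activation phase, slower logistic
decay (width ≈ 2 stages) ≈ 3.5 stages later — on top of a constitutive
lognormal baseline (median 30). Phases come from four activation waves
(centres spread over the stage axis, jitter sd 0.7), or from a uniform
stagger in `staggered_phases` mode. Monotone-only activation curves were
rejected at design time: with eight stages every pair of monotone curves
correlates above the significance threshold, which would make
co-expression filtering uninformative and would not produce the circular
standardized-profile geometry that angular ordering requires. The pulse
family keeps activation order well defined and restores both properties.
Total transcriptional output is stabilized in two steps: the baseline keeps
stage sums comparable, and the residual activation-wave imbalance is
absorbed into the baseline component (pulse shapes untouched), so
per-million normalization returns exactly the planted profiles. Counts are
negative-binomial (gamma–Poisson, dispersion 0.1, 3 RNA replicates, equal
library sizes); dispersion 0 yields the deterministic noiseless limit.

**Network.** Twenty TFs in four families are drafted from singleton genes
whose promoter peak assigns back to themselves. Families form three-tier
cascades (TF→TF, one-stage lag); each TF regulates five targets (one triad
member each, fraction ≥ 0.15, self-assigning promoter) that inherit the
TF's trajectory with a one-stage lag. TF family base phases sit in
[1.5, 3.0] stages so every planted pair's noiseless lag-1 correlation
clears the n=8 significance threshold. Network genes carry no constitutive
baseline (stage-specific regulators), which keeps planted correlations
intact under normalization and noise. Each TF has its own motif; every
planted edge is realized as a motif hit inside the target's promoter ACR,
plus 40 decoy hits in random promoters emulating the non-functional
remainder of a footprint-filtered hit list.

**Peaks and marks.** Expressed genes (stage mean ≥ 25% of their maximum)
get promoter ATAC peaks; a third of genes also carry an exonic peak. Two
hundred transient distal peaks exist only at the burst stage (the 5th,
DPA8), 75% overlapping TEs; three hundred constant distal peaks span the
burst stage ± 1 at 40% TE overlap — the planted contrast behind the
TE-enrichment comparison. H3K27ac/H3K27me3 promoter peaks track/mirror
expression; H3K9me2 covers a subset of distal TEs; additional constant
distal mark peaks populate the non-TE intergenic space so the shuffled
background domain ("intergenic with any mark") contains both strata. Each
transient peak emits an ncRNA transcript at the burst stage; decoy
transcripts overlapping coding genes exercise the ncRNA filter. Promoter
accessibility signal leads expression by half a stage and scales with the
gene's amplitude.

**Ancestors.** For each gene a target correlation is drawn around its
class value (conserved 0.95, middle 0.5, dysfunction 0.0; sd 0.03) and the
ancestor profile is constructed in the normalized-expression space as
`rho·ẑ + sqrt(1−rho²)·ê⊥` around the gene's noiseless profile, so the
planted Pearson r is exact by construction; measurement noise attenuates
it downstream.

**What the generator does not emulate.** Read-level artefacts (mappability,
GC bias, duplicates), peak-boundary drift between stages, realistic TE
families, linkage between neighbouring genes' expression, branching or
asynchronous development, and biological replicate structure beyond i.i.d.
negative-binomial noise. Passing recovery tests therefore demonstrates the
correctness and calibration of the pipeline's logic under its stated model,
not performance on raw sequencing data.

## Problem sizes and determinism

Default analyses run on the full synthetic genome (1600 genes, ~2300 union
ACRs) in seconds; tests use a reduced genome (80 triads, 0.7 Mb
chromosomes) where full size adds nothing, and ten full-size seeds where
across-seed behaviour is the claim. The ordering-recovery construction uses
200 genes with uniformly staggered phases, balanced triads, no constitutive
baseline and a minimal planted network, so that the measured quantity is
ordering fidelity rather than phase ties or baseline contamination.
A single global seed fans out to per-module streams by stable hashing of
module names; all outputs are byte-reproducible given seed and config, and
every written file carries the tool version and a config hash in its
header.

## Known limitations

* The DEG stand-in (Welch on log2 counts) is less powerful than a
  negative-binomial GLM at low counts; its type-I calibration is tested,
  its power curve is not matched to any count model.
* The enrichment p-value pools shuffles into one Fisher table, which
  treats shuffle draws as independent Bernoulli trials; for very small
  `n_shuffles` the p-value is optimistic relative to a permutation p.
* Angular ordering assumes a single dominant temporal circle; data with
  two independent trajectories would interleave their ranks.
* k-means divergence clustering is data-driven: cluster boundaries move
  with the r distribution. The threshold mode exists for fixed boundaries.
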