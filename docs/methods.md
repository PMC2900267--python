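# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Design and input model

The unit of analysis is a genes × arrays matrix of log2 expression
summaries with a design mapping each array to one of ≥ 2 time groups
(each with ≥ 2 arrays). The reference design is five groups of
4, 6, 5, 8, 8 arrays (31 total), labelled day 0/2/7/21/60. Probe-level
processing (background correction, RMA summarization, probe filtering) is
upstream of this package: the pipeline starts from the summary matrix.
Missing values are rejected rather than imputed.

## Normalization

**Quantile normalization** maps every column onto the across-array mean of
order statistics. Ties within a column receive the mean of the reference
values over their shared rank span, which makes the map deterministic.
Exactly equal columns are a fixed point; on tie-free columns the map is
idempotent and every column ends with the identical multiset of values.
With ties those two statements hold only approximately — the averaging
rule slightly smooths tied spans (the same behaviour as limma's
`normalizeQuantiles`).

**Gene-wise profile normalization** rescales each gene to

    ŷ_nm = (y_nm − ȳ_n) / max_m |y_nm − ȳ_n|

so every non-constant gene is centered at zero with maximum absolute value
exactly 1. This removes per-gene magnitude so clustering sees only profile
shape. The denominator is the unique center-based scale that confines the
values to [−1, 1] with the bound attained. Constant genes (zero
denominator) are set to zero, flagged degenerate, and excluded from
clustering — a constant gene has no direction of change to cluster on.
The transform is invariant to positive affine per-gene changes
(a·y + b ↦ same ŷ), which the test suite checks as a property.

## Differential expression

Each gene is scored by three one-way-ANOVA-style statistics across the
time groups. All three share the classical decomposition (between-group
and within-group sums of squares with k − 1 and M − k degrees of freedom);
within-group variance is floored at machine epsilon times the gene's mean
square so noise-free fixtures give a large finite F rather than infinity.

**Moderated F.** The residual variance is shrunk toward a prior:
s̃²g = (d₀s₀² + d·s²g)/(d₀ + d). The hyperparameters (d₀, s₀²) are
estimated by matching the mean and variance of log s²g to the
scaled-F marginal implied by an inverse-chi-square prior (digamma/trigamma
moment equations, trigamma inverted by Newton iteration). p-values come
from F(k−1, d₀+d). When the observed spread of log s²g does not exceed the
sampling spread, d₀ = ∞ and every gene receives the common variance; in
the exactly-degenerate case (all s²g identical) the common value is that
shared variance, so moderation is a no-op, and with d₀ = 0 the statistic
reduces to the classical F — both limits are tested.

**Windowed regularized F (Cyber-T style).** Genes are ranked by mean
expression; the background variance of a gene is the mean s² over a
centered window of `window_size` genes (default 101, truncated at the
edges), combined as (n₀·bg + d·s²)/(n₀ + d) with n₀ = 10 prior
observations, and referred to F(k−1, n₀+d). n₀ = 0 recovers the classical
test exactly.

**Multiclass SAM.** d = r/(s + s₀) with
r = √((n/∏nₖ)·Σₖ nₖ(x̄ₖ − x̄)²) and s = √(pooled within-variance · Σₖ 1/nₖ);
for two groups at s₀ = 0 this is the ordinary two-sample t. The fudge
factor s₀ is the grid point (0, 5, …, 100th percentiles of s) minimizing
the coefficient of variation of the windowed median absolute deviation of
d across s-quantile windows. The null distribution comes from label
permutations (default 1,000; enumerated exhaustively when fewer distinct
assignments exist). Per-gene FDR at cutoff |d_g| is the π₀-corrected
median over permutations of the permuted exceedance count divided by the
observed count; π₀ is the samr-style quartile estimate.

**FDR for the p-value tests.** The p-value ensemble is fitted by maximum
likelihood with a beta-uniform mixture λ·U(0,1) + (1−λ)·Beta(r, s)
(box constraints λ ∈ [10⁻⁴, 1−10⁻⁴], r, s ∈ [0.01, 100]; three fixed
starting points). The uniform weight is not identifiable when the beta
component is itself near-uniform, so the null weight used in the FDR
formula is the conservative uniform floor π₀ = min_p f̂(p) of the fitted
density (≥ λ, equal to λ whenever the beta component vanishes at its
flattest point). FDR(t) = π₀·t / F̂(t), monotone-repaired in t. If no
optimizer restart converges, Benjamini–Hochberg step-up values are used
with a logged warning.

**Conglomerate call.** The conglomerate score is the mean of the three
per-test ranks (ties broken by gene id for determinism); the conglomerate
FDR is the per-gene median of the three FDRs made non-decreasing along the
conglomerate ordering by a running maximum; genes at FDR ≤ α (default
0.02) are called. The combination rule is deliberately the simplest
order-statistic aggregate "equally weighting" the three tests; it is a
documented choice, not a published formula.

## Consensus clustering

K-means (random-point initialization, Lloyd iterations capped at 300,
Euclidean distance on the normalized rows) is run `repeats` = 30 times for
each k = 6…14, i.e. 270 runs. The co-occurrence matrix C holds the exact
fraction of runs in which each gene pair shared a cluster; D = 1 − C is
the consensus dissimilarity. Ward linkage on D (via the Lance–Williams
update, accepting that D is not Euclidean — a standard approximation) cut
at K gives the consensus partition; K defaults to 12 and is deliberately a
user parameter, supported by a stability table (mean within-cluster vs
between-cluster co-occurrence across K) rather than an automatic
selection. Per-cluster profiles are the mean ± sd of normalized expression
per group. Genes that co-cluster in most runs have D ≈ 0 and group
robustly; incidental co-clusterings average out, which is why the
consensus is cleaner than hierarchical clustering of the raw data.

**Optimal leaf ordering.** Heatmap/dendrogram leaves are ordered to
minimize the total dissimilarity of adjacent leaves over all
dendrogram-consistent orders, with an exact bottom-up dynamic program (two
min-plus matrix products with backpointers per merge). The exact program
is cubic and is applied up to 300 leaves; larger maps fall back to scipy's
fast reordering. (The DP is authored here because scipy's
`optimal_leaf_ordering` returned measurably non-minimal orders on random
small instances; the test suite checks the DP against exhaustive
enumeration on ≤ 8 leaves.)

## Term enrichment and grouping

For a cluster of size n from a background of B genes, a term with `total`
members in the background and `count` in the cluster gets the one-sided
hypergeometric upper-tail p = P(X ≥ count). No multiple-testing correction
is applied across terms (the reporting rule is raw p < 0.03, as in the
original analysis); an EASE-style jackknife variant (count − 1) is
available as a flag. Terms are grouped on the overlap coefficient
|A∩B|/min(|A|,|B|) ≥ 0.70 of their cluster-restricted member sets —
overlap rather than Jaccard because the intent is that specific terms
subsumed by general ones group together. Groups are connected components
(overlap chains group transitively); a group is significant if its best
member has p < 0.03, and its representative is the most specific
significant member (smallest background total; ties by p, then term id).
Ontology-graph propagation is out of scope — specificity is proxied by
background frequency.

## Motif over-representation

Each PWM becomes a log-odds scorer against the background base
composition estimated from the background promoter set (Laplace-floored so
absent bases stay finite): W_bj = log(((c_bj + pc·q_b)/(Σc_j + pc))/q_b)
with pseudocount pc = 0.01. A window is a hit when its score reaches
`threshold_fraction` = 0.80 of the motif's maximum achievable score; both
strands are scanned, overlapping hits all count, windows containing N are
skipped. A PWM whose maximum log-odds score is ≤ 0 (indistinguishable from
background) is flagged degenerate and produces no hits.

For foreground windows W with pooled background hit rate p̂,
Z = (O − Wp̂)/√(Wp̂(1−p̂)); cells with p̂ ∈ {0, 1} or zero variance are
reported as missing, never as 0. Z > 3 is reported as over-represented and
Z < −3 as under-represented. The binomial null treats windows as
independent; when planted/real sites clump strongly within a few
promoters, the analytic Z is mildly anti-conservative relative to a
promoter-level resampling null — the test suite bounds the discrepancy
(sign agreement, |ΔZ| ≤ 0.5) at moderate enrichment, which is the regime
the |Z| > 3 rule addresses.

The Z matrix is visual-summarized by two-way Ward/Euclidean clustering
after scaling each cluster's Z vector to unit variance (sample sd;
constant or undefined columns are dropped with a warning) and by PCA of
the per-cluster Z vectors (features centered, covariance
eigen-decomposed, component signs fixed so the largest-magnitude loading
is positive).

## Synthetic studies and what they show

The generator plants exactly the structure each stage assumes:
per-gene baselines uniform on [6, 12] log2 units, i.i.d. Gaussian noise
(default sd 0.5 log2 units), twelve built-in profile shapes spanning
monotone, transient and delayed responses with amplitude 2.0 (4× noise —
a strong but not degenerate signal; the amplitude scale is a free
parameter of the generator since no effect-size scale is prescribed by
the design), Poisson-planted motif sites drawn from PWM columns at
non-overlapping positions, and annotation terms sampling members with a
relative weight (default 20) on the target cluster. One master seed fans
out to per-stage substreams; identical seeds give byte-identical outputs.

Deliberately not emulated: array/batch effects (assumed removed by
quantile normalization upstream), probe-level artifacts,
correlated gene-gene noise, realistic promoter sequence composition and
repeat structure, and ontology DAG structure. Passing recovery tests
therefore demonstrates the correctness and calibration of the downstream
mathematics under its own assumptions, not robustness to those real-data
complications.

Benchmark problem sizes, chosen to exercise the study-scale conditions at
desk scale: FDR calibration uses 10,000 genes (10% planted) × 50
replicates with 100 SAM permutations; cluster recovery uses 12 planted
profiles × 40 genes over 10 seeds with the full 270-run scan; motif
calibration uses 12 clusters × 25 promoters of 1,200 bp with one planted
motif (3 extra sites/promoter over a 0.25 background rate) × 10
replicates.

## Known limitations

- The conglomerate combination (mean rank, median FDR) is a transparent
  stand-in for the original study's unpublished combination rule.
- The binomial motif null ignores within-promoter site clumping (see
  above) and double-counts palindromic double-strand hits.
- Ward on 1 − C is a pragmatic convention; 1 − C is not a Euclidean
  metric.
- The beta-uniform mixture assumes a single beta component; grossly
  multimodal p-value distributions would be better served by the BH
  fallback.
- K (consensus cluster count) is a judgment call by design; the stability
  diagnostic informs but does not automate it.
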