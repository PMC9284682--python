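# Methods

## Data model

Counts are nonnegative integers, genes × samples on disk (TSV with gene ids
in the first column, or MatrixMarket with `genes.tsv`/`samples.tsv` id
sidecars); all statistics operate on samples × features, and the transpose
happens once at the I/O boundary. Sample metadata is a TSV with required
columns `sample_id`, `group`, `batch`, `p_low`; extra columns are carried
as opaque annotations. `p_low` must lie in [0, 1]. A missing `p_low` is a
hard error whenever a quality-based operation needs it — silent imputation
would corrupt the very statistic the package is built around — but tables
with gaps can still be loaded and used for quality-free operations.

## Normalization

Size factors are median-of-ratios: s_j = median over genes g of
c_gj / geomean_g(c), restricted to genes with strictly positive counts in
every sample (a zero anywhere zeroes the geometric mean). Expression is
then log2(c/s + pseudocount), pseudocount 1 by default. This is a
deliberate, documented substitute for a regularized-log transform: the
downstream adjusted PCA and distance-based cluster metrics need a
variance-stabilized log scale, not exact ridge-shrunken values. The
differential-expression stage is likewise a substitute: per-gene two-sided
Wilcoxon rank-sum between two groups (exact null for small tie-free
groups, tie-corrected normal approximation otherwise), Benjamini–Hochberg
adjustment, DEG = adjusted p < 0.05. It is meant as a soft indicator of
correction quality, not as a publication-grade DE method; its DEG counts
are not comparable to counts from a negative-binomial GLM. On corrected
data, DE runs on the normalized values with the confounder design
regressed out gene-wise (least squares), not on the reduced PC scores.

## Batch detection and design bias

The Kruskal–Wallis statistic uses midranks with the standard tie
correction, H' = H / (1 − ΣT/(N³−N)), T = t³ − t per tie group, and a
chi-square upper-tail p-value with k − 1 degrees of freedom. The datasets
this tool targets have tens of samples, where the chi-square approximation
is standard practice; an exact/Monte-Carlo permutation p-value is
available for small-sample cross-checks, with a mid-p option because a
continuous tail approximation should be compared to the discrete
permutation null at half weight on the observed value. Enumeration shows
the approximation tracks the exact mid-p uniformly within 0.05 for
near-balanced two-group designs at N ≤ 8 (e.g. 3+3, 5+3) but not for all
small designs (2+2+2 can deviate by ~0.1); the validity tests therefore
use near-balanced two-group designs. All-identical values are a defined
degenerate case, (H, p) = (0, 1): a constant quality score carries no
batch signal and must not crash a pipeline.

Design bias is (γ + 1)/2 where γ is the Pearson correlation of
|p_low_i − p_low_j| over all unordered pairs with the 0/1 different-group
indicator. Distance on p_low is plain absolute difference (1-D Euclidean);
no rescaling, since p_low is already a probability. Constant p_low makes γ
undefined and is defined to return 0.5 — no information either way.

## Confounder-adjusted PCA

The confounder design Y concatenates a centered one-hot batch block, a
standardized (mean 0, sd 1) p_low column, and/or externally supplied
columns such as surrogate variables — combined correction is a joint
kernel, not sequential correction, because sequential correction is
order-dependent. The penalty kernel is linear, K = YYᵀ scaled so
trace(K) = n. Components are the top-k eigenvectors of the symmetrized
Xᵀ(I − λK)X for column-centered X; at λ = 0 this is PCA. For wide matrices
(p > n) the eigenproblem is restricted to the row space of X via its SVD
(an r × r problem, exact for all nonzero eigenvalues) — eigenvalues agree
with the dense p-space decomposition to 1e-8 in tests. Each component's
sign is fixed so its largest-magnitude loading entry is positive, making
outputs reproducible.

Two related quantities are kept deliberately distinct:

* the **penalty** uses the trace-normalized K inside the eigenproblem;
* the **diagnostic ratio** per component is the fraction of the score's
  variance explained by the confounder columns — the same quadratic-form
  ratio with the orthogonal projector onto col(Y) as kernel — so it lives
  on an absolute [0, 1] scale (a tolerance of 1 is vacuous, 0 demands
  exact orthogonality).

λ is the smallest value on a grid (default 0…20 in 41 steps) whose top-k
components all have diagnostic ratio ≤ tol (default 0.05, i.e. at most 5 %
of any retained component's variance attributable to the confounder). If
no grid value qualifies, the minimizer of the worst ratio is returned with
a non-convergence flag. With ~40 samples a noise covariate explains ~1/n ≈
2.5 % of a random direction's variance, so an uninformative p_low usually
(not always) selects λ = 0; this matters for the behavior of quality
correction when quality is unrelated to the batch (below).

## Outlier rule

Sort p_low ascending and scan consecutive gaps restricted to the upper
half of the sorted values; if the largest such gap is ≥ `min_gap`
(default 0.3), every sample above it is an outlier. Restricting to the
upper half means spread among good-quality samples can never flag them —
the rule targets a sudden increase in high values only. Ties in the gap
scan resolve to the topmost gap (fewest samples removed). Alternatives: a
fixed p_low threshold, or an explicit id list for reproducing removals
chosen by eye. An empty outlier set is a valid result, and the pipeline's
outliers-removed variants then equal their outliers-kept twins exactly.

## Cluster metrics

All three metrics use Euclidean distances on the first two (configurable)
component scores, with biological groups as clusters: Pearson gamma
(correlation of distances with the different-cluster indicator, higher
better), dunn1 (minimum between-cluster distance over maximum
within-cluster diameter — a worst-case index; all-singleton clusterings
return +inf, identical points 0), and wb.ratio (mean within- over mean
between-cluster distance, lower better). Degenerate embeddings report
gamma 0 / dunn 0 with an explicit flag rather than NaN so JSON reports
stay machine-readable. Before/after deltas record the sample counts on
both sides: the metrics are sensitive to removing samples, and no
adjustment for that is attempted — variants with changed n are flagged in
the comparison table instead.

## Simulator

Counts are negative binomial with variance μ + φμ² (φ = dispersion, 0.1 by
default — a typical bulk RNA-seq value). Per-gene baselines are lognormal
(σ = 1) around `baseline_mean` (50) so size-factor estimation sees a
realistic spread. A fraction of genes (10 %) carries a group effect
(log2FC 1.5 in the lexicographically last group) and a disjoint fraction
(10 %) a batch effect (log2FC 2 in the lexicographically last batch).
Quality is p_low = clip(base + shift·[shifted batch] + N(0, sd), 0, 1)
with base 0.2, shift 0.4, sd 0.05. The `quality_coupling` knob scales the
per-sample batch-effect magnitude by p_low/max(p_low): at 1 the batch
artifact is proportional to how poor the sample is (the quality-coupled
regime), at 0 it is a flat multiplier unrelated to quality. Coupling acts
only on the batch genes, keeping group signal orthogonal to quality by
construction. The default design is 2 groups × 2 batches × 10 samples
(40 samples, 2000 genes); compact studies use 4 per cell (16 samples,
1000 genes). All randomness flows from one seed through a single
generator. Outlier injection raises k random samples' p_low by 0.5
(capped at 1) and multiplies their counts gene-wise by lognormal(0, σ)
noise.

What the simulator does not emulate: library-size gradients within batch,
count overdispersion heterogeneity across genes, correlated gene modules,
more than one affected batch, and any read-level artifacts. Passing tests
show the machinery behaves correctly under the stated generative model,
not that real datasets obey that model.

## Behavior under the two regimes

With a quality-coupled batch effect (coupling 1, p_low shift 0.4), p_low
correction removes the batch structure from the leading components
(|corr(score, batch)| < 0.3) and its Pearson-gamma gain matches true-batch
correction within 0.1 in ≥ 80 % of seeds at 16 samples × 1000 genes.

With a quality-independent batch effect (coupling 0, shift 0), true-batch
correction improves gamma while p_low correction is near-neutral
(|Δγ| < 0.05) in most seeds — but not uniformly: at 40 samples a pure-noise
covariate has chance correlation with batch or group of typical magnitude
1/√n ≈ 0.16, occasionally large enough that the selected λ > 0 and the
forced orthogonalization either partially corrects the batch by accident
(Δγ > 0.05) or strips some group signal (Δγ < −0.05). This is an intrinsic
finite-sample property of correcting by an uninformative covariate, not a
numerical artifact; the per-seed deltas track corr(p_low, batch/group)
directly. Users should read the design-bias statistic and the KW p-value
before trusting a quality-based correction.

## Numerical choices and limitations

* Eigen-solves use symmetric (`eigh`) decompositions on explicitly
  symmetrized matrices; loadings are orthonormal to 1e-8.
* Non-centered input to the adjusted PCA is rejected (tolerance
  1e-6 × scale) rather than silently centered, so score/loading consistency
  is the caller's contract.
* The pipeline runs all eight variants even when no outliers are found,
  guaranteeing twin equality rather than special-casing.
* Summary JSON is written with sorted keys and no timestamps; identical
  inputs and seed give byte-identical files.
* Only two-group DE is supported; multi-group designs skip DEG counting.
* Plots are intentionally out of the pipeline's load-bearing path and are
  not implemented; all results are tabular/JSON.
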