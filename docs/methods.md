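# Methods

This note documents the models implemented in `tumortraj`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic data generator does and does not emulate.

## Synthetic data generator (`simdata`)

The generator emulates a multi-sample droplet scRNA-seq tumor study:
26 samples by default (12 control, 14 double-mutant), balanced sexes and
two stages (P40, P90), with per-cell UMI counts drawn gene-wise from a
negative binomial around

```
mean_gc = library_size_c × softmax_g( baseline_g
                                      + population_offset_g(pop_c)
                                      + Σ_p loading_gp · program_p(t_c)
                                      + batch_gs )
```

* `baseline_g ~ Normal(0, 1.2)` on the log scale.  The spread 1.2 was
  calibrated once so that, at the default 2 000 genes, cells hit the
  design's depth targets: median ≈ 1 000 UMIs and ≈ 500 detected genes
  per cell.
* Tumor-lineage cells carry a latent pseudotime `t ∈ [0, 1]` drawn from
  a stage-specific Beta (`P40: Beta(2, 4)`, `P90: Beta(4, 2)` by
  default, plus a per-sample logit-scale shift with σ = 0.25 that
  induces within-sample correlation).  Population labels (basal tumor,
  CSC1, CSC2, luminal Clu+) are the quartile windows of `t`.
* Three expression programs ride on `t`: EMT
  `1 − σ((t − 0.35)/0.08)` (falls), Wnt
  `exp(−(t − 0.45)²/(2·0.07²))` (mid bump), luminal
  `σ((t − 0.75)/0.08)` (rises late).  Tumor marker blocks ramp on and
  off smoothly (sigmoid edges, width 0.04) so the lineage is a
  continuum rather than four disconnected islands — the property that
  makes a diffusion map appropriate in the first place.
* Genotype acts as a symmetric log-odds shift of tumor-lineage
  membership (default 5.0: ≈ 20 % of mutant cells and ≈ 0.2 % of
  control cells are tumor lineage; the CSC populations come out at
  2–5 % of all cells, deliberately rare but testable — per-population
  frequencies are not pinned down by any external number).  Setting the
  shift and the sex/stage effects to zero yields an exchangeable null
  dataset.
* Mitochondrial reads get a per-cell Beta-distributed share (mean 0.05,
  concentration 30), so a realistic tail of cells fails the 15 %
  filter.  Ribosomal genes (`Rps/Rpl` prefixes) are uniformly elevated.
* All draws come from one counter-based Philox stream keyed by the
  master seed; identical seeds give bit-identical matrices.

Not emulated: ambient RNA contamination, doublets, epitope (protein)
counts, and batch structure beyond a per-sample log-normal gene effect.
Passing tests on this generator therefore show that the statistics are
implemented correctly and calibrated under the intended model — not
that they are robust to artifacts the generator omits.

The barcode-mixture generator (for knee testing) draws `n_real`
log-normal cell totals over an `n_ambient` geometric (exponential-tail)
background; a real-to-ambient depth ratio of at least ~10× is
recommended for a well-defined knee.

## Barcode knee (`preprocess.knee_select`)

The knee is the point of maximum perpendicular distance to the chord on
the curve of **log cumulative count vs log rank** (both axes scaled to
[0, 1]).  The log on the cumulative axis matters: with 50 000 ambient
barcodes of mean depth 20 against 500 cells of depth 1 000, the ambient
pool holds about two thirds of all counts, and the distance-to-chord
maximum of the *raw* cumulative fraction sits deep inside the cell
shoulder (rank ≈ 100), while on the log scale it recovers the planted
boundary (ranks 424–455 across seeds for 500 planted cells).  The rule
is deterministic, tuning-free, and scale-invariant in the totals.

## QC, normalization, features (`preprocess`)

* Thresholds are read literally: **at least** 100 genes (≥), **less
  than** 15 % mitochondrial content (<), and, for the epitope-profiled
  variant, less than 2 500 genes (<).  If no mitochondrial genes are
  flagged the criterion is skipped with a warning.
* Normalization: per-cell depth scaling to `scale_factor` (default
  10⁴) then log1p.  Optional covariate regression replaces each gene by
  the residual of a linear fit on centered covariates plus the gene
  intercept; a constant covariate therefore drops out exactly.
* Highly variable genes: mean and dispersion (variance/mean) are
  computed on the de-logged (expm1) scale; the log dispersion is
  **median-centered within 20 quantile bins of mean expression** and
  the top genes taken.  Centering rather than z-scoring is deliberate:
  when many genuinely variable genes share a bin they inflate the
  bin's spread, and dividing by it suppresses exactly the genes one
  wants — with 50 planted bimodal genes in one bin, z-scoring recovers
  0/50 while centering recovers 50/50.
* Informative PC count: a parallel-analysis permutation test — every
  gene's values fully shuffled across cells per permutation, a PC
  significant while its eigenvalue exceeds the 95th percentile of its
  permutation null, counted with a prefix (stop-at-first-failure) rule.
  Partial per-gene shuffling is available but not the default: a null
  built from 99 %-intact copies of the data tracks the observed
  eigenvalue so closely that pure noise yields false positives.
* Clustering: shared-nearest-neighbor graph (Jaccard weights on k = 20
  neighborhoods) with Leiden modularity optimization at the given
  resolution, seeded.  The 2D embedding contract is any seeded
  neighbor-preserving method; t-SNE (PCA initialization) is used.
  Exactly duplicated rows may embed at near- but not exactly
  coincident points.  A `merge_labels` utility supports explicit manual
  merging of indistinguishable clusters.

## Mixing statistic (`mixing`)

`D_j = Σ_i q_i log(q_i/q_i⁰)` in nats, with `0·log 0 := 0`; `q⁰` never
contains zeros because groups absent from the data are dropped.
Neighborhoods are the k = 30 nearest neighbors in PCA space, self
excluded, distance ties broken by cell index.  The permutation null
shuffles labels uniformly across cells and recomputes `D` against the
unchanged `q⁰`; the one-sided empirical p is `(1 + #{null ≥ obs}) /
(n_perm + 1)`.  Under i.i.d. labels the mean of `D` is ≈ (|I|−1)/(2k)
(chi-square approximation).

The "how much of the divergence is biology" summary is the exact KL
chain rule over the nested grouping replicate ⊂ biological group:
`D_total = D_between + Σ_b q_b D_within(b)` holds per cell to machine
precision, and the reported fraction is `mean(D_between) /
mean(D_total)`.  This is one specific operationalization of
variance-explained for neighborhood composition; it is exact and
additive, but not comparable to ANOVA-style estimators.

## Density contrast and refinement filters (`density`)

The per-cell contrast is `log2((f_A + ε)/(f_B + ε))` where `f_A, f_B`
are group-wise Gaussian KDEs (Scott's rule per group) evaluated at each
cell's 2D coordinates and `ε = 10⁻³ × max(f_A, f_B)` keeps values
finite where one group is absent.  Swapping groups negates every value
exactly.

Two refinement rules operate on the 2D embedding (Euclidean distances):
remove cells farther than 3 SD from their cluster centroid (SD of the
cluster's own centroid distances; singletons kept with a warning;
coincident clusters keep everything since `0 > 0` is false), and remove
cells whose k = 10 nearest neighbors give a **strict** majority
(> k/2) to one single label different from the cell's own — ties keep
the cell.  The majority filter is intentionally applied once; a second
pass sees a changed vote base and is not idempotent.

## Pseudobulk differential expression (`de`)

Counts are summed exactly per (sample, group); empty columns are
dropped.  Size factors are median-of-ratios over genes nonzero in all
columns (geometric mean 1), with a logged total-count fallback.  Genes
must be detected in at least 5 % of the relevant cells (inclusive) to
be tested.

Per gene the model is `log μ = Xβ + log(size factor)` with NB2 variance
`μ + αμ²`, fitted by Fisher scoring alternated with dispersion updates.
The dispersion estimator matches the Pearson chi-square to its residual
degrees of freedom (`Σ (y−μ)²/(μ+αμ²) = n − p`); profile ML is
available as an option but is biased low at a dozen pseudobulk columns,
which inflates Wald type-I error (measured ≈ 0.12 with a normal
reference vs ≈ 0.05 for the default).  The Wald statistic on the
contrast coefficient is referred to `t(n − p)`; the multi-group LRT
statistic divided by its degrees of freedom is referred to
`F(df, n − p_full)` — both are the finite-sample versions of the usual
asymptotic references and converge to them as columns accumulate.
The cell-count covariate enters as centered log10(cells) for scale
stability and is dropped automatically when constant.  Non-convergent
genes get `p = NA` and are excluded from the BH denominator (count in
the log).  Benjamini–Hochberg is the exact step-up procedure.

Known behavior: with a large unidirectional DE fraction (≳ 20 % of
genes) median-of-ratios absorbs part of the shift and fold changes
shrink; at 5 % DE the bias is ≤ 0.05 log2.

Composition testing uses a binomial random-intercept model per cluster:
`logit P(cell ∈ cluster) = Xβ + u_s`, `u_s ~ N(0, σ²)` per sample,
fitted by Gauss–Hermite (25-node) marginal maximum likelihood with an
approximate REML penalty `½ log|X'W_eff X|`
(`W_eff = 1/(1/(n p (1−p)) + σ²)`); Wald statistics are referred to
`t(samples − parameters)`.  Plain ML with a normal reference was
measured anticonservative (type-I 0.09 at 26 samples) while the
REML-penalized t-referenced version is calibrated (0.05) with an
unbiased σ̂.  Complete separation (a cluster confined to one design
cell) is flagged with `p = NA`; if the mixed fit fails, a beta-binomial
ML fit with the sample as overdispersion unit is used and labeled in
the status column.

The bulk comparison converts pooled single-cell profiles to a
per-million scale and computes Pearson correlation of log10 values over
genes strictly above 10⁻⁴ in every compared sample.

## Gene sets and module scores (`genesets`)

Enrichment of a set in a DE result is an unequal-variance (Welch)
two-sample t-test of member vs non-member log2 fold changes, two-sided,
with the direction given by the sign of the member mean; sets with
fewer than 3 expressed members are skipped.  Reporting keeps sets with
BH q < 0.1 and |mean log2 FC| strictly > 0.5, and drops sets with
strictly more than 10 % ribosomal members.  Gene sets are read from GMT
files; a 14-symbol stemness marker list is packaged as a constant
(the non-unique symbol "Aldh1a" is stored verbatim and matched by
prefix, with the matches logged).

Module scores are the classic binned-control construction: genes binned
into 25 quantile bins of dataset-average expression; per set gene, 100
control genes drawn from its bin (without replacement when the bin
allows); score = mean(set) − mean(pooled controls) per cell.  All-zero
genes are excluded from binning and control pools, so padding the
matrix with silent genes cannot change a score.  Scores are computed on
normalized (optionally kNN-smoothed) expression; the kNN average
(`trajectory.neighbor_smooth`) is a deliberately simple smoother, off
by default, standing in for heavier imputation schemes.

## Trajectory (`trajectory`)

Diffusion map: union kNN graph (k_kernel = 15), Gaussian kernel with
per-cell local scale σ_i = distance to the k-th neighbor
(`w_ij = exp(−d²/(σ_i σ_j))`), self-loops added, anisotropic
normalization with α = 1 to remove density effects, then the
symmetrized row-stochastic operator's eigendecomposition.  The trivial
eigenvalue is checked to equal 1 (tolerance 10⁻⁸) and dropped;
coordinates are eigenvectors scaled by their eigenvalues with a
largest-entry-positive sign convention.  A disconnected kernel graph is
an error naming the component sizes; `on_disconnected="bridge"` instead
joins components through their nearest cell pairs, which is the right
tool when an analysis deliberately removes an intermediate population
and only the end-to-end ordering is of interest.  Local kernel scaling
was chosen over a global bandwidth for robustness to the very uneven
densities of rare populations.

Pseudotime is the diffusion distance to a root cell,
`‖(λ_i/(1−λ_i))(ψ_i(x) − ψ_i(root))‖` over components whose weight
λ/(1−λ) is at least 1 % of the leading one, min–max scaled to [0, 1].
With a root *cluster*, the root cell is the cluster's extreme cell on
DC1, anchoring the origin at the designated starting population (the
basal tumor population in this design); the direction of a diffusion
trajectory is not identifiable from the spectrum alone, so this
biological anchor is the orientation rule.

LOESS: first-degree locally weighted regression with tricube weights on
the span-fraction nearest points (default span 0.5); the 95 % band uses
the equivalent-kernel norm with a global residual variance.  The
trajectory curve is each diffusion coordinate smoothed over pseudotime
on an even 100-point grid.

Per-sample reproducibility reruns the diffusion map and pseudotime on
every sample with strictly more than 10 cells in the relevant
populations and reports |Spearman ρ| against the global pseudotime.
The stage-shift test is cell-level OLS of pseudotime on stage over
double-mutant samples with at least 5 qualifying cells, with standard
errors clustered by sample and a `t(clusters − 2)` reference (measured
type-I 0.06 vs 0.10 for the normal reference at 12 samples).

## Pipeline and formats (`pipeline`, `io`, `cli`)

Stages run in method order, each consuming a sub-seed derived from the
master seed and the stage name, so runs are byte-identical and toggling
one stage leaves the others' outputs unchanged.  All tables are
TSV/UTF-8 with headers; matrices are Matrix Market triplets (1-based).
Unknown configuration keys are rejected, and the fully resolved
configuration is written next to the outputs.  The barcode-knee stage
is off by default because simulated matrices contain only called cells.
Mitochondrial/ribosomal flags come from configurable symbol-prefix
rules (`mt-`; `Rps`/`Rpl`).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run everything at desk
scale, chosen to exercise the same designs at a fraction of the cost:
26 × 40–60 cells for the end-to-end runs, ~800 tumor cells × 12 samples
for trajectory recovery, 2 000 genes × 12 pseudobulk columns for DE
calibration, 400–500 replicates for the composition and stage-shift
null rates, and per-gene NB dispersions log-normal around 0.025 — the
typical within-genotype biological dispersion of inbred-mouse
replicates — at pooled depths of ~10⁶ UMIs per sample.

## Known limitations

* The KL chain-rule fraction is one defensible definition of
  "variance explained by biology"; other estimators will give other
  numbers on the same data.
* The NB machinery has no dispersion shrinkage across genes; with very
  few columns per group, per-gene dispersion estimates are noisy and
  power is correspondingly conservative.
* Trajectory direction is fixed only by the designated origin cluster;
  on data where the origin is unknown the sign of pseudotime is
  arbitrary.
* t-SNE determinism holds for a fixed seed, platform and library
  version; embeddings are contracts, not canonical coordinates.
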