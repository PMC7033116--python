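# tumortraj

Reusable building blocks for droplet single-cell RNA-seq studies that
compare tumor-bearing and control tissue across many replicate samples:
quality control and clustering, an entropy-based statistic for how well
samples mix in a pooled analysis, differential abundance on 2D
embeddings, pseudobulk differential expression, gene-set scoring, and
diffusion-map trajectory reconstruction of tumorigenesis.  A synthetic
data generator with planted ground truth (populations, pseudotime,
expression programs) makes every step testable without any download.

The package is written for analysts working on designs like a mouse
salivary-gland squamous-cell-carcinoma model: dozens of single-gland
libraries (control and double-mutant genotypes, two stages, both sexes,
~500 genes and ~1000 UMIs per cell), a rare cancer-stem-cell-like
compartment, and a tumor lineage running basal → CSC1 → CSC2 →
luminal along a latent pseudotime.

## The statistics at the core

**Sample mixing (`tumortraj.mixing`).** For each cell *j* with
neighborhood *N(j)* (k = 30 nearest neighbors in PCA space), the
Kullback–Leibler divergence of the local group composition from the
global one,

```
D_j = Σ_{i∈I} q_i log(q_i / q_i⁰)          (natural log)
```

where `q_i` is the share of group *i* in *N(j)* and `q_i⁰` its share in
the whole dataset.  `D_j = 0` means perfect mixing; the maximum
`ln(1/q_i⁰)` is a pure neighborhood of the rarest group.  A shuffle null
gives the expected value under exchangeability (≈ (|I|−1)/(2k) for
i.i.d. labels), and an exact chain-rule decomposition splits the
replicate-level divergence into a biological-factor part (genotype, sex,
stage) and a residual replicate part:
`D_total = D_between + Σ_b q_b D_within(b)`.

**Pseudobulk DE (`tumortraj.de`).** Counts are pooled per
(sample, group), normalized with median-of-ratios size factors, and each
gene is fitted with a negative-binomial log-linear model with centered
log10 cell count as covariate.  Two-level contrasts use a Wald test with
a t reference on the residual degrees of freedom; the four trajectory
populations are compared with a likelihood-ratio test referred to an F
distribution.  Cell-type composition shifts are tested with a binomial
random-intercept (per-sample) model fitted by Gauss–Hermite marginal
likelihood with an approximate REML penalty.

**Trajectory (`tumortraj.trajectory`).** A diffusion map on highly
variable genes (local-scale Gaussian kernel, anisotropic normalization),
diffusion pseudotime as the spectrally weighted distance to a root cell
in the origin population, LOESS smoothing of coordinates, expression and
module scores over pseudotime, a per-sample reproducibility check, and a
cluster-robust linear model for early-vs-late stage shifts along the
trajectory.

## Worked example

```python
from scipy.stats import spearmanr
from tumortraj import (SimConfig, simulate_dataset, TUMOR_POPULATIONS,
                       normalize_log, select_hvg, diffusion_map,
                       diffusion_pseudotime)

cfg = SimConfig(seed=1, n_samples_control=0, n_samples_mutant=12,
                cells_per_sample=70, tumor_fraction=0.95,
                genotype_effect=0.0)
counts, metadata, truth = simulate_dataset(cfg)

tumor = truth.population.isin(TUMOR_POPULATIONS)
expr = normalize_log(counts.loc[:, tumor.to_numpy()])
hvg = select_hvg(expr, 300)
res = diffusion_map(expr.loc[hvg], n_comps=10, k_kernel=15)
pt = diffusion_pseudotime(res, root_cluster="basal_tumor",
                          cluster_labels=truth.population[tumor])
print(f"rho = {spearmanr(pt, truth.pseudotime[tumor])[0]:.3f}")
print(pt.groupby(truth.population[tumor]).median().sort_values().round(3))
```

prints

```
rho = 0.989
basal_tumor    0.041
CSC1           0.418
CSC2           0.834
luminal_Clu    0.987
```

i.e. the inferred pseudotime recovers the planted ordering (Spearman
ρ = 0.989 against the latent *t*) and the four populations appear in the
expected basal → CSC1 → CSC2 → luminal order of median pseudotime.

The same dataset can be pushed through the whole chain with the driver
(`tumortraj run --seed 1 --out results/`), which writes one TSV per
stage (QC, PCA, clusters, mixing, density, composition, DE, scores,
trajectory) plus the fully resolved configuration; reruns are
byte-identical.  The CLI also exposes each stage as a subcommand
(`simulate`, `knee`, `qc`, `cluster`, `mixqc`, `density`, `refine`,
`composition`, `de`, `enrich`, `score`, `trajectory`).

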