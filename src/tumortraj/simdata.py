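"""Synthetic droplet scRNA-seq data with a planted tumor trajectory.

Generates UMI count matrices that mimic a two-genotype (control vs
double-mutant), two-stage (P40 vs P90), mixed-sex study design of 26
salivary-gland samples profiled by droplet single-cell RNA-seq.  Mutant
samples carry a four-population tumor lineage (basal tumor -> CSC1 ->
CSC2 -> luminal Clu+) laid out on a latent pseudotime t in [0, 1], with
three expression programs riding on it:

* EMT      — high at the start, decays (decreasing sigmoid),
* Wnt      — Gaussian bump in the CSC window,
* luminal  — rises late (increasing sigmoid).

Counts are negative-binomial (gamma-Poisson) around per-cell expected
profiles: gene mean = library_size x softmax-normalised
exp(baseline + population offset + program loading x program(t) + batch).
Ground truth (population, pseudotime, design) is returned for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_barcode_mixture",
    "TUMOR_POPULATIONS",
]

#: Ordered tumor lineage; pseudotime windows tile [0, 1] in this order.
TUMOR_POPULATIONS = ("basal_tumor", "CSC1", "CSC2", "luminal_Clu")

#: Default pseudotime windows, one per tumor population, tiling [0, 1].
DEFAULT_WINDOWS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0))

#: Default non-tumor cell types: (name, base proportion, marker block size).
DEFAULT_CELLTYPES = (
    ("acinar", 0.28, 30),
    ("ductal", 0.18, 30),
    ("duct_sex", 0.08, 20),
    ("basal_normal", 0.12, 30),
    ("luminal", 0.10, 30),
    ("myoepithelial", 0.07, 20),
    ("immune", 0.07, 20),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults emulate the real design: 12 control + 14 double-mutant
    samples, a median of roughly 1000 UMIs and 500 detected genes per
    cell, rare CSC populations (a few percent of mutant cells), and a
    stage-dependent pseudotime distribution (early-stage samples sit
    earlier on the trajectory).
    """

    n_genes: int = 2000
    n_samples_control: int = 12
    n_samples_mutant: int = 14
    cells_per_sample: int | tuple[int, int] = 120
    celltype_table: tuple = DEFAULT_CELLTYPES
    tumor_populations: tuple = TUMOR_POPULATIONS
    pseudotime_windows: tuple = DEFAULT_WINDOWS
    #: baseline tumor-lineage share at genotype_effect = 0; the genotype
    #: shift moves this to ~20% in mutants and ~0.2% in controls at the
    #: default effect size
    tumor_fraction: float = 0.02
    #: marker block size per tumor population
    tumor_marker_block: int = 25
    #: genes per expression program (EMT, Wnt, luminal)
    program_block: int = 40
    #: (center, width, amplitude) of each program shape on t in [0, 1]
    emt_params: tuple[float, float, float] = (0.35, 0.08, 2.0)
    wnt_params: tuple[float, float, float] = (0.45, 0.07, 2.0)
    luminal_params: tuple[float, float, float] = (0.75, 0.08, 2.0)
    #: log-odds shift of tumor-lineage membership in mutant vs control
    #: samples; 0 gives a null dataset with exchangeable genotypes
    genotype_effect: float = 5.0
    #: log-odds shift of the sex-dimorphic duct population (F vs M)
    sex_effect: float = 0.8
    #: Beta(a, b) pseudotime parameters at each stage
    stage_effect: dict = field(
        default_factory=lambda: {"P40": (2.0, 4.0), "P90": (4.0, 2.0)}
    )
    #: sd of a per-sample logit-scale pseudotime shift (sample clustering)
    stage_sample_sd: float = 0.25
    #: median library size (UMIs/cell) and log-normal sigma
    library_size_median: float = 1000.0
    library_size_sigma: float = 0.35
    #: per-gene NB overdispersion (var = mu + phi mu^2)
    nb_dispersion: float = 0.3
    #: mean mitochondrial read share per cell (Beta-distributed around it)
    mito_fraction_mean: float = 0.05
    mito_fraction_conc: float = 30.0
    n_mito_genes: int = 13
    n_ribo_genes: int = 60
    #: sd of the per-sample, per-gene log-scale batch effect
    batch_effect_sd: float = 0.10
    #: sd of the log-normal gene baseline (controls genes/cell)
    baseline_sigma: float = 1.2
    marker_log_fc: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.tumor_populations) != len(self.pseudotime_windows):
            raise ValueError("one pseudotime window per tumor population required")
        prev_hi = 0.0
        for name, (lo, hi) in zip(self.tumor_populations, self.pseudotime_windows):
            if not (0.0 <= lo < hi <= 1.0) or abs(lo - prev_hi) > 1e-12:
                raise ValueError(
                    f"pseudotime window {lo, hi} of population {name!r} does not "
                    "tile [0, 1] in order"
                )
            prev_hi = hi
        if abs(prev_hi - 1.0) > 1e-12:
            raise ValueError(
                f"pseudotime windows end at {prev_hi}, not 1.0 "
                f"(last population {self.tumor_populations[-1]!r})"
            )
        base = sum(p for _, p, _ in self.celltype_table)
        if base <= 0:
            raise ValueError("celltype base proportions must be positive")
        if not 0 <= self.tumor_fraction < 1:
            raise ValueError("tumor_fraction must be in [0, 1)")
        for st in ("P40", "P90"):
            if st not in self.stage_effect:
                raise ValueError(f"stage_effect missing stage {st!r}")


@dataclass
class GroundTruth:
    """Latent state of a simulated dataset."""

    population: pd.Series  # per-cell true population label
    pseudotime: pd.Series  # per-cell true t in [0,1]; NaN outside tumor lineage
    program_loadings: pd.DataFrame  # genes x (emt, wnt, luminal)
    sample_design: pd.DataFrame  # sample -> genotype, sex, stage


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def program_activities(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """EMT / Wnt / luminal program activity at pseudotime ``t`` (cells x 3)."""
    ec, ew, _ = config.emt_params
    wc, ww, _ = config.wnt_params
    lc, lw, _ = config.luminal_params
    emt = 1.0 - _sigmoid((t - ec) / ew)
    wnt = np.exp(-((t - wc) ** 2) / (2.0 * ww**2))
    lum = _sigmoid((t - lc) / lw)
    return np.column_stack([emt, wnt, lum])


def _sample_design(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g, n in (("control", config.n_samples_control),
                 ("double_mutant", config.n_samples_mutant)):
        for i in range(n):
            rows.append({
                "sample": f"{'C' if g == 'control' else 'M'}{i + 1:02d}",
                "genotype": g,
                # alternate deterministically for balance
                "sex": "F" if i % 2 == 0 else "M",
                "stage": "P40" if (i // 2) % 2 == 0 else "P90",
            })
    return pd.DataFrame(rows).set_index("sample")


def _gene_table(config: SimConfig) -> pd.DataFrame:
    names = []
    for i in range(config.n_mito_genes):
        names.append(f"mt-Sim{i + 1}")
    for i in range(config.n_ribo_genes):
        prefix = "Rps" if i % 2 == 0 else "Rpl"
        names.append(f"{prefix}sim{i + 1}")
    i = 0
    while len(names) < config.n_genes:
        names.append(f"Gene{i + 1:05d}")
        i += 1
    genes = pd.DataFrame({"gene": names[: config.n_genes]}).set_index("gene")
    genes["mito"] = genes.index.str.lower().str.startswith("mt-")
    genes["ribo"] = genes.index.str.startswith(("Rps", "Rpl"))
    return genes


def simulate_dataset(config: SimConfig):
    """Draw a full synthetic dataset.

    Returns
    -------
    counts : pd.DataFrame
        genes x cells integer UMI matrix.
    metadata : pd.DataFrame
        per-cell sample, genotype, sex, stage (index = barcode). Also
        carries the gene table as ``metadata.attrs['genes']``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.Generator(np.random.Philox(key=config.seed))

    design = _sample_design(config, rng)
    genes = _gene_table(config)
    n_genes = config.n_genes

    # --- gene architecture -------------------------------------------------
    baseline = rng.normal(0.0, config.baseline_sigma, size=n_genes)
    # ribosomal genes are uniformly high; mito handled via per-cell share
    ribo_idx = np.flatnonzero(genes["ribo"].to_numpy())
    baseline[ribo_idx] += 1.5
    mito_idx = np.flatnonzero(genes["mito"].to_numpy())

    celltypes = [name for name, _, _ in config.celltype_table]
    all_pops = celltypes + list(config.tumor_populations)
    pop_offsets = {p: np.zeros(n_genes) for p in all_pops}

    free = np.flatnonzero(~(genes["mito"] | genes["ribo"]).to_numpy())
    cursor = 0

    def take(n):
        nonlocal cursor
        block = free[cursor:cursor + n]
        cursor += n
        if len(block) < n:
            raise ValueError("n_genes too small for the requested marker blocks")
        return block

    marker_blocks = {}
    for name, _, block in config.celltype_table:
        idx = take(block)
        marker_blocks[name] = idx
        pop_offsets[name][idx] += config.marker_log_fc
    for name in config.tumor_populations:
        idx = take(config.tumor_marker_block)
        marker_blocks[name] = idx
        pop_offsets[name][idx] += config.marker_log_fc
    # sex-specific markers ride on the duct_sex population
    sex_block = take(10)

    loadings = np.zeros((n_genes, 3))
    prog_amp = [config.emt_params[2], config.wnt_params[2], config.luminal_params[2]]
    prog_blocks = []
    for j in range(3):
        idx = take(config.program_block)
        prog_blocks.append(idx)
        loadings[idx, j] = prog_amp[j] * rng.uniform(0.5, 1.5, size=len(idx))
    program_loadings = pd.DataFrame(
        loadings, index=genes.index, columns=["emt", "wnt", "luminal"]
    )

    # --- per-sample composition -------------------------------------------
    base_props = np.array([p for _, p, _ in config.celltype_table], float)
    base_props = base_props / base_props.sum() * (1.0 - config.tumor_fraction)
    duct_sex_i = celltypes.index("duct_sex") if "duct_sex" in celltypes else None

    all_counts = []
    meta_rows = []
    true_pop = []
    true_t = []
    cell_names = []

    for sample, row in design.iterrows():
        if isinstance(config.cells_per_sample, tuple):
            lo, hi = config.cells_per_sample
            n_cells = int(rng.integers(lo, hi + 1))
        else:
            n_cells = int(config.cells_per_sample)

        # genotype shifts the tumor-lineage log-odds symmetrically
        half = config.genotype_effect / 2.0
        shift = half if row["genotype"] == "double_mutant" else -half
        pt = config.tumor_fraction
        logit = np.log(pt / (1 - pt)) + shift if 0 < pt < 1 else -np.inf
        p_tumor = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(logit) else 0.0

        props = base_props.copy()
        if duct_sex_i is not None and config.sex_effect != 0:
            sh = config.sex_effect / 2.0
            sh = sh if row["sex"] == "F" else -sh
            props[duct_sex_i] *= np.exp(sh)
        props = props / props.sum() * (1.0 - p_tumor)
        full_props = np.append(props, p_tumor)

        comp = rng.choice(len(full_props), size=n_cells, p=full_props)
        is_tumor = comp == len(celltypes)

        a, b = config.stage_effect[row["stage"]]
        t = np.full(n_cells, np.nan)
        n_t = int(is_tumor.sum())
        if n_t:
            tt = rng.beta(a, b, size=n_t)
            # per-sample logit-scale shift -> within-sample correlation
            if config.stage_sample_sd > 0:
                u = rng.normal(0.0, config.stage_sample_sd)
                tt = np.clip(tt, 1e-9, 1 - 1e-9)
                tt = _sigmoid(np.log(tt / (1 - tt)) + u)
            t[is_tumor] = tt

        pops = np.array([celltypes[c] if c < len(celltypes) else "" for c in comp],
                        dtype=object)
        if n_t:
            edges = np.array([w[1] for w in config.pseudotime_windows])
            which = np.searchsorted(edges, t[is_tumor], side="right")
            which = np.minimum(which, len(config.tumor_populations) - 1)
            pops[is_tumor] = np.array(config.tumor_populations, dtype=object)[which]

        # --- expression profiles ------------------------------------------
        log_mu = np.tile(baseline, (n_cells, 1))
        for p in celltypes:
            m = pops == p
            if m.any():
                log_mu[m] += pop_offsets[p]
        if n_t:
            # tumor marker blocks ramp on/off smoothly in pseudotime so the
            # lineage is a continuum, as in the tissue, not four islands
            tt = t[is_tumor]
            for p, (lo, hi) in zip(config.tumor_populations,
                                   config.pseudotime_windows):
                m_p = np.ones_like(tt)
                if lo > 0:
                    m_p *= _sigmoid((tt - lo) / 0.04)
                if hi < 1:
                    m_p *= _sigmoid((hi - tt) / 0.04)
                log_mu[is_tumor] += m_p[:, None] * pop_offsets[p][None, :]
            acts = program_activities(tt, config)
            log_mu[is_tumor] += acts @ loadings.T
        if duct_sex_i is not None:
            m = pops == "duct_sex"
            if m.any():
                sgn = 1.0 if row["sex"] == "F" else -1.0
                log_mu[np.ix_(m, sex_block)] += sgn * config.marker_log_fc
        if config.batch_effect_sd > 0:
            log_mu += rng.normal(0.0, config.batch_effect_sd, size=n_genes)

        prof = np.exp(log_mu)
        prof[:, mito_idx] = 0.0
        prof /= prof.sum(axis=1, keepdims=True)
        # mito share per cell, Beta around the configured mean
        mfm, conc = config.mito_fraction_mean, config.mito_fraction_conc
        if mfm > 0 and len(mito_idx):
            share = rng.beta(mfm * conc, (1 - mfm) * conc, size=n_cells)
            prof *= (1.0 - share)[:, None]
            prof[:, mito_idx] = (share / len(mito_idx))[:, None]

        lib = rng.lognormal(np.log(config.library_size_median),
                            config.library_size_sigma, size=n_cells)
        mu = prof * lib[:, None]
        phi = config.nb_dispersion
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(np.int64)

        all_counts.append(counts)
        names = [f"{sample}_c{i + 1:04d}" for i in range(n_cells)]
        cell_names.extend(names)
        for name in names:
            meta_rows.append({"cell": name, "sample": sample, **row.to_dict()})
        true_pop.append(pops)
        true_t.append(t)

    counts = pd.DataFrame(
        np.concatenate(all_counts, axis=0).T, index=genes.index, columns=cell_names
    )
    metadata = pd.DataFrame(meta_rows).set_index("cell")
    metadata.attrs["genes"] = genes
    truth = GroundTruth(
        population=pd.Series(np.concatenate(true_pop), index=cell_names,
                             name="population"),
        pseudotime=pd.Series(np.concatenate(true_t), index=cell_names,
                             name="pseudotime"),
        program_loadings=program_loadings,
        sample_design=design,
    )
    return counts, metadata, truth


def simulate_barcode_mixture(
    n_real: int,
    n_ambient: int,
    real_depth: float = 1000.0,
    ambient_depth: float = 20.0,
    seed: int = 0,
    real_sigma: float = 0.35,
):
    """Barcode total-UMI mixture: log-normal cells over an ambient tail.

    Real cells draw totals from a log-normal with the given median depth;
    ambient barcodes draw geometric (exponential-tail) totals with the
    given mean.  A ratio real_depth/ambient_depth of at least ~10x is
    recommended for a well-defined knee.

    Returns
    -------
    totals : np.ndarray of int, sorted descending
    is_real : np.ndarray of bool, aligned with ``totals``
    """
    if n_real <= 0:
        raise ValueError("n_real must be positive: no knee exists without cells")
    if n_ambient < 0:
        raise ValueError("n_ambient must be non-negative")
    rng = np.random.Generator(np.random.Philox(key=seed))
    real = np.maximum(
        1, np.round(rng.lognormal(np.log(real_depth), real_sigma, n_real))
    ).astype(np.int64)
    if n_ambient:
        p = min(1.0, 1.0 / ambient_depth)
        ambient = rng.geometric(p, size=n_ambient).astype(np.int64)
    else:
        ambient = np.empty(0, dtype=np.int64)
    totals = np.concatenate([real, ambient])
    labels = np.concatenate([np.ones(n_real, bool), np.zeros(n_ambient, bool)])
    order = np.lexsort((np.arange(len(totals)), -totals))
    return totals[order], labels[order]
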