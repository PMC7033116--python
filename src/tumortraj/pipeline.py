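"""Pipeline driver: configuration, logging and stage orchestration.

Runs the stages in method order — simulate/ingest, barcode knee, QC,
normalization, HVG selection, PCA, clustering, 2D embedding, mixing QC,
density contrast, embedding-filter refinement, composition tests,
pseudobulk DE, gene-set scores, trajectory — writing one TSV per stage
plus a structured log line (stage, parameters, sizes, wall time).
Every stochastic stage draws a sub-seed derived from the master seed
and the stage name, so reruns are byte-identical and stages can be
toggled without disturbing one another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import density as density_mod
from . import genesets as genesets_mod
from . import io as io_mod
from . import mixing as mixing_mod
from . import preprocess as pp
from . import simdata
from . import trajectory as traj_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All stage toggles and parameters; defaults follow the study rules."""

    input_path: str | None = None  # None -> simulate
    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulate
    n_genes: int = 2000
    cells_per_sample: int = 60
    n_samples_control: int = 12
    n_samples_mutant: int = 14
    # stages on/off
    run_knee: bool = False
    run_mixqc: bool = True
    run_density: bool = True
    run_refine: bool = True
    run_composition: bool = True
    run_de: bool = True
    run_scores: bool = True
    run_trajectory: bool = True
    # qc
    min_genes: int = 100
    max_genes: int | None = None
    max_mito_frac: float = 0.15
    # normalize / features
    scale_factor: float = 1e4
    n_hvg: int = 500
    n_pcs: int = 15
    # clustering / embedding
    cluster_resolution: float = 1.0
    k_neighbors: int = 20
    # mixing
    mixing_k: int = 30
    # filters
    outlier_n_sd: float = 3.0
    majority_k: int = 10
    # DE
    de_min_frac: float = 0.05
    # trajectory
    traj_n_comps: int = 10
    traj_k_kernel: int = 15
    loess_span: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


def _log_stage(name, t0, **info):
    logger.info("stage=%s wall=%.2fs %s", name, time.time() - t0,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    truth = None

    # --- ingest / simulate -------------------------------------------------
    t0 = time.time()
    if config.input_path is None:
        sim_cfg = simdata.SimConfig(
            n_genes=config.n_genes,
            cells_per_sample=config.cells_per_sample,
            n_samples_control=config.n_samples_control,
            n_samples_mutant=config.n_samples_mutant,
            seed=stage_seed(config.seed, "simulate"),
        )
        counts, metadata, truth = simdata.simulate_dataset(sim_cfg)
        genes = metadata.attrs["genes"]
        counts.attrs["genes"] = genes
    else:
        counts = io_mod.read_counts(config.input_path)
        genes = counts.attrs["genes"]
        meta_path = Path(config.input_path) / "metadata.tsv"
        if meta_path.exists():
            metadata = pd.read_csv(meta_path, sep="\t").set_index("cell")
        else:
            metadata = pd.DataFrame(index=counts.columns)
            metadata["sample"] = "sample1"
    _log_stage("ingest", t0, n_genes=counts.shape[0], n_cells=counts.shape[1])

    # --- knee (optional; simulated matrices contain only called cells) ----
    if config.run_knee:
        t0 = time.time()
        totals = np.sort(counts.sum(axis=0).to_numpy())[::-1]
        cut = pp.knee_select(totals)
        keep_cells = counts.sum(axis=0) >= totals[cut - 1]
        counts = counts.loc[:, keep_cells]
        metadata = metadata.loc[counts.columns]
        _log_stage("knee", t0, cutoff_rank=cut, n_cells=counts.shape[1])

    # --- QC ----------------------------------------------------------------
    t0 = time.time()
    thr = pp.QCThresholds(min_genes=config.min_genes,
                          max_genes=config.max_genes,
                          max_mito_frac=config.max_mito_frac)
    keep, qc = pp.qc_filter(counts, thr, genes)
    io_mod.write_tsv(qc.assign(keep=keep).rename_axis("cell"), out / "qc.tsv")
    counts = counts.loc[:, keep.to_numpy()]
    metadata = metadata.loc[counts.columns]
    _log_stage("qc", t0, kept=int(keep.sum()), removed=int((~keep).sum()))

    # --- normalize / HVG / PCA --------------------------------------------
    t0 = time.time()
    expr = pp.normalize_log(counts, config.scale_factor)
    hvg = pp.select_hvg(expr, min(config.n_hvg, expr.shape[0]))
    pca, expl = pp.pca_embed(expr.loc[hvg], config.n_pcs)
    io_mod.write_tsv(pca.rename_axis("cell"), out / "pca.tsv")
    _log_stage("normalize_pca", t0, n_hvg=len(hvg), n_pcs=config.n_pcs)

    # --- cluster / embed ---------------------------------------------------
    t0 = time.time()
    clusters = pp.cluster_graph(pca, config.k_neighbors,
                                config.cluster_resolution,
                                seed=stage_seed(config.seed, "cluster"))
    emb = pp.embed_2d(pca, seed=stage_seed(config.seed, "embed"))
    cell_table = emb.assign(cluster=clusters).rename_axis("cell")
    _log_stage("cluster_embed", t0, n_clusters=clusters.nunique())

    # --- mixing QC ---------------------------------------------------------
    if config.run_mixqc:
        t0 = time.time()
        k = min(config.mixing_k, len(pca) - 1)
        neighbors = mixing_mod.knn_graph(pca.to_numpy(), k)
        rep = metadata["sample"]
        factors = [c for c in ("genotype", "sex", "stage") if c in metadata]
        if factors:
            fmap = {s: "|".join(str(metadata.loc[metadata["sample"] == s,
                                                 f].iloc[0]) for f in factors)
                    for s in rep.unique()}
            dec = mixing_mod.decompose_mixing(neighbors, rep, fmap)
            io_mod.write_tsv(dec.rename_axis("cell"), out / "mixing.tsv")
            frac = dec.attrs["fraction_between"]
        else:
            mix = mixing_mod.mixing_divergence(neighbors, rep)
            io_mod.write_tsv(mix.divergence.to_frame().rename_axis("cell"),
                             out / "mixing.tsv")
            frac = float("nan")
        _log_stage("mixqc", t0, k=k, fraction_between=round(frac, 4)
                   if frac == frac else "na")

    # --- density contrast --------------------------------------------------
    if config.run_density and "genotype" in metadata:
        t0 = time.time()
        contrast = density_mod.relative_log_density(emb, metadata["genotype"])
        io_mod.write_tsv(contrast.log2_ratio.to_frame().rename_axis("cell"),
                         out / "density.tsv")
        _log_stage("density", t0)

    # --- refinement filters ------------------------------------------------
    if config.run_refine:
        t0 = time.time()
        keep1 = density_mod.centroid_outlier_filter(emb, clusters,
                                                    config.outlier_n_sd)
        keep2 = density_mod.knn_majority_filter(emb, clusters,
                                                min(config.majority_k,
                                                    len(emb) - 1))
        refined = keep1 & keep2
        cell_table = cell_table.assign(keep=refined)
        _log_stage("refine", t0, removed=int((~refined).sum()))
    io_mod.write_tsv(cell_table, out / "cells.tsv")

    # --- composition -------------------------------------------------------
    if config.run_composition and "genotype" in metadata:
        t0 = time.time()
        comp = pd.crosstab(metadata["sample"], clusters)
        sample_design = metadata.groupby("sample", observed=True).first()
        rows = []
        for cl in comp.columns:
            try:
                res = de_mod.composition_test(comp, cl, sample_design)
            except ValueError as exc:
                logger.warning("composition: cluster %s skipped (%s)", cl, exc)
                continue
            for term, r in res.iterrows():
                rows.append({"cluster": cl, "term": term, **r.to_dict()})
        io_mod.write_tsv(pd.DataFrame(rows), out / "composition.tsv")
        _log_stage("composition", t0, n_clusters=comp.shape[1])

    # --- pseudobulk DE -----------------------------------------------------
    de_result = None
    if config.run_de and "genotype" in metadata:
        t0 = time.time()
        meta_de = metadata.copy()
        meta_de["all"] = "all"
        pb = de_mod.aggregate_pseudobulk(counts, meta_de, "all")
        gene_keep = de_mod.expression_fraction_filter(
            counts, min_frac=config.de_min_frac)
        pb.counts = pb.counts.loc[gene_keep.to_numpy()]
        de_result = de_mod.nb_wald_test(pb, "genotype")
        io_mod.write_tsv(de_result.rename_axis("gene"), out / "de_genotype.tsv")
        _log_stage("de", t0, n_genes=int(gene_keep.sum()),
                   n_failed=de_result.attrs["n_failed"])

    # --- gene-set scores ---------------------------------------------------
    if config.run_scores:
        t0 = time.time()
        scores = pd.DataFrame(index=expr.columns)
        score_sets: dict = {}
        if truth is not None:
            pl = truth.program_loadings
            score_sets = {prog: list(pl.index[pl[prog] > 0])
                          for prog in pl.columns}
        score_sets["stemness"] = list(genesets_mod.STEMNESS_GENES)
        for name, genes_in_set in score_sets.items():
            try:
                scores[name] = genesets_mod.module_score(
                    expr, genes_in_set,
                    seed=stage_seed(config.seed, "scores"))
            except ValueError:
                logger.info("scores: set %r absent from this dataset", name)
        io_mod.write_tsv(scores.rename_axis("cell"), out / "scores.tsv")
        if de_result is not None:
            ribo = genes["ribo"].reindex(de_result.index).fillna(False)
            enr = genesets_mod.set_enrichment_test(
                de_result["log2fc"].astype(float),
                {**score_sets},
                ribo_flags=ribo)
            if len(enr):
                io_mod.write_tsv(enr.rename_axis("set"), out / "enrichment.tsv")
        _log_stage("scores", t0)

    # --- trajectory --------------------------------------------------------
    if config.run_trajectory and truth is not None:
        t0 = time.time()
        pops = truth.population.reindex(expr.columns)
        tumor = pops.isin(simdata.TUMOR_POPULATIONS)
        if tumor.sum() >= config.traj_n_comps + 2:
            sub = expr.loc[hvg, tumor.to_numpy()]
            res = traj_mod.diffusion_map(sub, config.traj_n_comps,
                                         config.traj_k_kernel)
            pt = traj_mod.diffusion_pseudotime(
                res, root_cluster="basal_tumor", cluster_labels=pops[tumor])
            curve = traj_mod.fit_trajectory_curve(res, span=config.loess_span)
            table = res.coords.assign(pseudotime=pt,
                                      population=pops[tumor])
            io_mod.write_tsv(table.rename_axis("cell"), out / "trajectory.tsv")
            io_mod.write_tsv(curve, out / "trajectory_curve.tsv")
            _log_stage("trajectory", t0, n_cells=int(tumor.sum()))
        else:
            logger.warning("trajectory: too few tumor cells (%d)", int(tumor.sum()))

    if truth is not None:
        gt = pd.DataFrame({"population": truth.population,
                           "pseudotime": truth.pseudotime}).rename_axis("cell")
        io_mod.write_tsv(gt.loc[gt.index.intersection(expr.columns)],
                         out / "ground_truth.tsv")
    return out
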