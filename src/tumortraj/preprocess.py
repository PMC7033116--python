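"""Barcode selection, QC, normalization, feature selection and clustering.

Implements the upstream half of the droplet scRNA-seq workflow: knee-point
barcode calling on the rank-vs-cumulative-count curve, cell QC on detected
genes and mitochondrial content (at least ``min_genes`` genes, strictly
less than ``max_mito_frac`` mitochondrial share), depth normalization with
optional covariate regression, binned-dispersion highly-variable-gene
selection, PCA with a permutation test for the number of informative
components, shared-nearest-neighbor modularity clustering, and a seeded
2D neighbor embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "knee_select",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "pca_embed",
    "significant_pcs",
    "cluster_graph",
    "embed_2d",
    "merge_labels",
]


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    ``min_genes`` is inclusive ("at least"), ``max_genes`` and
    ``max_mito_frac`` are strict upper bounds ("less than").
    """

    min_genes: int = 100
    max_genes: int | None = None
    max_mito_frac: float = 0.15

    def __post_init__(self):
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not 0 < self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in (0, 1]")
        if self.max_genes is not None and self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")


def knee_select(barcode_totals: np.ndarray) -> int:
    """Number of barcodes to keep at the knee of the rank/count curve.

    The log cumulative count is plotted against log rank, both axes
    scaled to [0, 1]; the knee is the point of maximum perpendicular
    distance to the chord joining the first and last points.  The log
    on the cumulative axis keeps the huge ambient tail from swamping
    the real-cell shoulder; the cutoff is scale-invariant in the
    totals.  All barcodes at rank <= the returned cutoff are selected.
    """
    totals = np.asarray(barcode_totals, dtype=np.float64)
    if totals.ndim != 1 or len(totals) < 3:
        raise ValueError("need at least 3 barcode totals")
    if np.any(np.diff(totals) > 0):
        raise ValueError("barcode totals must be sorted in descending order")
    if totals[-1] <= 0:
        raise ValueError("barcode totals must be positive")
    ranks = np.arange(1, len(totals) + 1, dtype=np.float64)
    x = np.log(ranks)
    x = x / x[-1]
    y = np.log(np.cumsum(totals))
    if y[-1] == y[0]:  # single barcode dominates; no knee beyond rank 1
        return 1
    y = (y - y[0]) / (y[-1] - y[0])
    # perpendicular distance to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(np.argmax(dist) + 1)


def qc_metrics(counts: pd.DataFrame, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell QC table: detected genes, total UMIs, mitochondrial fraction."""
    if genes is None:
        genes = counts.attrs.get("genes")
    mat = counts.to_numpy()
    out = pd.DataFrame(index=counts.columns)
    out["detected_genes"] = (mat > 0).sum(axis=0)
    out["total_umis"] = mat.sum(axis=0)
    if genes is not None and "mito" in genes and genes["mito"].any():
        mito = mat[genes["mito"].to_numpy(bool)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["mito_frac"] = np.where(out["total_umis"] > 0,
                                        mito / out["total_umis"], 0.0)
    else:
        out["mito_frac"] = np.nan
    return out


def qc_filter(counts: pd.DataFrame, thresholds: QCThresholds | None = None,
              genes: pd.DataFrame | None = None):
    """Keep cells passing gene-count and mitochondrial-content cutoffs.

    Returns (kept mask aligned with cells, per-cell QC table).  If no
    mitochondrial genes are flagged, the mito criterion is skipped with
    a warning.
    """
    thresholds = thresholds or QCThresholds()
    qc = qc_metrics(counts, genes)
    keep = qc["detected_genes"] >= thresholds.min_genes
    if thresholds.max_genes is not None:
        keep &= qc["detected_genes"] < thresholds.max_genes
    if qc["mito_frac"].isna().all():
        warnings.warn("no mitochondrial genes flagged; mito criterion skipped")
        logger.warning("qc_filter: mito criterion skipped (no flags)")
    else:
        keep &= qc["mito_frac"] < thresholds.max_mito_frac
    return keep, qc


def normalize_log(counts: pd.DataFrame, scale_factor: float = 1e4,
                  regress_covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Depth-normalize to ``scale_factor`` counts per cell, then log1p.

    With ``regress_covariates`` (cells x covariates), each gene's values
    are replaced by the residuals of a linear fit on the covariates with
    the gene-wise intercept added back.
    """
    depth = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(depth == 0):
        bad = counts.columns[depth == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    expr = np.log1p(counts.to_numpy(dtype=float) / depth * scale_factor)
    if regress_covariates is not None:
        # covariates centered so the intercept is the gene mean and a
        # constant (degenerate) covariate drops out exactly
        cov = np.asarray(regress_covariates, dtype=float)
        cov = cov - cov.mean(axis=0, keepdims=True)
        X = np.column_stack([np.ones(expr.shape[1]), cov])
        beta, *_ = np.linalg.lstsq(X, expr.T, rcond=None)
        expr = (expr.T - X[:, 1:] @ beta[1:]).T
    return pd.DataFrame(expr, index=counts.index, columns=counts.columns)


def select_hvg(expr: pd.DataFrame, n_top: int, n_bins: int = 20) -> pd.Index:
    """Top genes by dispersion standardized within mean-expression bins.

    Mean and dispersion (variance/mean) are computed on the de-logged
    (expm1) normalized scale, where technical count noise is homogeneous
    across expression levels; the log dispersion is centered on its
    median within 20 quantile bins of mean expression (removing the
    mean-dispersion trend without letting a bin's own spread — inflated
    when many genuinely variable genes share a bin — mask the signal)
    and the top ``n_top`` genes returned.  Fully deterministic (ties
    broken by gene order).
    """
    mat = np.expm1(expr.to_numpy())
    mean = mat.mean(axis=1)
    expressed = mean > 0
    if n_top > int(expressed.sum()):
        raise ValueError(
            f"n_top={n_top} exceeds {int(expressed.sum())} expressed genes")
    var = mat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
        log_disp = np.where(disp > 0, np.log(disp), -np.inf)
    # quantile bins on mean expression of expressed genes
    order = pd.Series(mean).rank(method="first")
    bins = pd.qcut(order[expressed], q=min(n_bins, int(expressed.sum())),
                   labels=False, duplicates="drop")
    z = np.full(len(mean), -np.inf)
    d = pd.Series(log_disp[expressed]).replace(-np.inf, np.nan)
    med = d.groupby(bins).transform("median")
    zz = (d - med).fillna(-np.inf)  # zero-dispersion genes rank last
    z[expressed] = zz.to_numpy()
    # stable deterministic ranking: centered dispersion desc, then gene order
    idx = np.lexsort((np.arange(len(z)), -z))[:n_top]
    return expr.index[np.sort(idx)]


def pca_embed(expr: pd.DataFrame, n_pcs: int):
    """PCA scores of cells (genes centered); signs fixed by convention.

    Each component's sign is chosen so its largest-magnitude gene
    loading is positive.  Returns (cells x n_pcs scores, explained
    variance per component).
    """
    mat = expr.to_numpy(dtype=float).T  # cells x genes
    n, g = mat.shape
    if n_pcs > min(n, g):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n, g)}")
    mat = mat - mat.mean(axis=0)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    sign = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    scores = u * s * sign
    explained = s**2 / (n - 1)
    coords = pd.DataFrame(scores, index=expr.columns,
                          columns=[f"PC{i + 1}" for i in range(n_pcs)])
    return coords, explained


def significant_pcs(expr: pd.DataFrame, n_pcs: int = 20, n_perm: int = 50,
                    alpha: float = 0.05, shuffle_frac: float = 1.0,
                    seed: int = 0) -> int:
    """Count of leading informative PCs by a permutation (parallel-analysis) null.

    For each permutation every gene's values are shuffled across cells
    (``shuffle_frac`` < 1 shuffles only that fraction per gene, which
    leaves most of the observed eigenvalue in place and is
    anticonservative on pure noise — full shuffling is the default) and
    the top eigenvalues recomputed; a PC counts as significant while its
    eigenvalue exceeds the (1 - alpha) quantile of its null, stopping at
    the first non-significant component.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    mat = expr.to_numpy(dtype=float).T  # cells x genes
    n, g = mat.shape
    n_pcs = min(n_pcs, min(n, g) - 1)
    if alpha == 1:
        return n_pcs

    def top_eigs(m):
        c = m - m.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        return (s[:n_pcs] ** 2) / (n - 1)

    obs = top_eigs(mat)
    rng = np.random.default_rng(seed)
    k = max(1, int(round(shuffle_frac * n)))
    null = np.empty((n_perm, n_pcs))
    for p in range(n_perm):
        perm = mat.copy()
        if shuffle_frac >= 1.0:
            for j in range(g):
                perm[:, j] = perm[rng.permutation(n), j]
        else:
            for j in range(g):
                rows = rng.choice(n, size=k, replace=False)
                perm[rows, j] = perm[rng.permutation(rows), j]
        null[p] = top_eigs(perm)
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    sig = obs > thresh
    n_sig = 0
    for ok in sig:
        if not ok:
            break
        n_sig += 1
    return n_sig


def _snn_graph(coords: np.ndarray, k: int):
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    seen = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            w = inter / union
            if w > 0:
                edges.append((a, b))
                weights.append(w)
    return edges, weights


def cluster_graph(pca_coords: pd.DataFrame, k_neighbors: int = 20,
                  resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """SNN-graph modularity (Leiden) clustering at the given resolution."""
    import igraph
    import leidenalg

    coords = np.asarray(pca_coords, dtype=float)
    n = len(coords)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    edges, weights = _snn_graph(coords, k_neighbors)
    graph = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.array(part.membership)
    index = pca_coords.index if hasattr(pca_coords, "index") else pd.RangeIndex(n)
    return pd.Series(labels.astype(str), index=index, name="cluster")


def embed_2d(pca_coords: pd.DataFrame, seed: int = 0,
             perplexity: float | None = None) -> pd.DataFrame:
    """Seeded neighbor-preserving 2D embedding (t-SNE) of PCA coordinates.

    Deterministic for a fixed seed on a fixed platform; downstream
    operations treat the coordinates as opaque.  Exactly duplicated
    input rows may embed at nearby but not exactly coincident points.
    """
    from sklearn.manifold import TSNE

    coords = np.asarray(pca_coords, dtype=float)
    n = len(coords)
    if n < 10:
        raise ValueError("need at least 10 cells for a 2D embedding")
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (n - 1) / 4))
    ts = TSNE(n_components=2, random_state=seed, init="pca",
              perplexity=min(perplexity, (n - 1) / 3.0))
    emb = ts.fit_transform(coords)
    index = pca_coords.index if hasattr(pca_coords, "index") else pd.RangeIndex(n)
    return pd.DataFrame(emb, index=index, columns=["dim1", "dim2"])


def merge_labels(labels: pd.Series, merge_map: dict[str, str]) -> pd.Series:
    """Explicitly merge cluster labels (e.g. indistinguishable subclusters)."""
    return labels.replace(merge_map)
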