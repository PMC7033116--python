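"""Embedding-space density contrasts and cell-filtering rules.

Compares the local abundance of two sample groups (e.g. control vs
double-mutant cells) on a 2D embedding via the log2 ratio of two
group-wise Gaussian kernel density estimates evaluated at every cell,
and provides the two visualization-filtering rules used downstream:
removal of cells more than ``n_sd`` standard deviations from their
cluster centroid, and removal of cells whose identity disagrees with a
strict majority of their k nearest embedding neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "DensityContrast",
    "relative_log_density",
    "centroid_outlier_filter",
    "knn_majority_filter",
]


@dataclass
class DensityContrast:
    """Per-cell log2 density ratio of group A over group B."""

    log2_ratio: pd.Series
    bandwidth_a: float
    bandwidth_b: float
    eps: float


def relative_log_density(embed2d, labels, group_a=None, group_b=None,
                         bandwidth: float | str = "auto",
                         eps_scale: float = 1e-3) -> DensityContrast:
    """log2 ratio of two group-wise 2D kernel densities at each cell.

    Each group's density is a Gaussian KDE (Scott's rule bandwidth when
    ``bandwidth='auto'``) normalized to integrate to 1, evaluated at the
    coordinates of every cell.  The ratio is regularized by eps =
    ``eps_scale`` x the maximum density over both groups, keeping values
    finite where one group is absent.  Swapping A and B negates every
    value exactly.
    """
    coords = np.asarray(embed2d, dtype=float)
    labels = pd.Series(labels, index=getattr(embed2d, "index", None))
    levels = pd.unique(labels)
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError("labels must have exactly 2 levels or "
                             "group_a/group_b must be given")
        group_a, group_b = sorted(levels, key=str)
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"group {group_a if not mask_a.any() else group_b!r} "
                         "is empty")
    bw = None if bandwidth == "auto" else bandwidth
    kde_a = gaussian_kde(coords[mask_a].T, bw_method=bw)
    kde_b = gaussian_kde(coords[mask_b].T, bw_method=bw)
    fa = kde_a(coords.T)
    fb = kde_b(coords.T)
    eps = eps_scale * max(fa.max(), fb.max())
    ratio = np.log2((fa + eps) / (fb + eps))
    return DensityContrast(
        log2_ratio=pd.Series(ratio, index=labels.index, name="log2_ratio"),
        bandwidth_a=float(kde_a.factor), bandwidth_b=float(kde_b.factor),
        eps=float(eps),
    )


def centroid_outlier_filter(embed2d, cluster_labels, n_sd: float = 3.0) -> pd.Series:
    """Keep cells within ``n_sd`` SDs of their cluster centroid.

    Per cluster: centroid = coordinate mean; a cell is removed iff its
    Euclidean distance to the centroid exceeds n_sd times the SD of the
    cluster's distances.  Singleton clusters are kept with a warning;
    coincident clusters (SD = 0) keep everything.
    """
    coords = np.asarray(embed2d, dtype=float)
    labels = pd.Series(cluster_labels, index=getattr(embed2d, "index", None))
    keep = np.ones(len(coords), dtype=bool)
    codes, cats = pd.factorize(labels)
    for c, lab in enumerate(cats):
        pos = np.flatnonzero(codes == c)
        if len(pos) < 2:
            logger.warning("centroid_outlier_filter: singleton cluster %r kept", lab)
            continue
        pts = coords[pos]
        dist = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        sd = dist.std(ddof=0)
        keep[pos] = ~(dist > n_sd * sd)
    return pd.Series(keep, index=labels.index, name="keep")


def knn_majority_filter(embed2d, cluster_labels, k: int = 10) -> pd.Series:
    """Keep cells agreeing with their k nearest embedding neighbors.

    A cell is removed iff strictly more than k/2 of its k nearest
    neighbors (Euclidean, ties broken by index) carry one single label
    different from the cell's own.  Ties and split votes keep the cell.
    Not idempotent: a second pass sees a changed vote base and is not
    applied by default.
    """
    from .mixing import knn_graph

    coords = np.asarray(embed2d, dtype=float)
    labels = pd.Series(cluster_labels, index=getattr(embed2d, "index", None))
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    neighbors = knn_graph(coords, k)
    codes, cats = pd.factorize(labels)
    keep = np.ones(n, dtype=bool)
    neigh_codes = codes[neighbors]
    for i in range(n):
        counts = np.bincount(neigh_codes[i], minlength=len(cats))
        top = int(np.argmax(counts))
        if top != codes[i] and counts[top] > k / 2.0:
            keep[i] = False
    return pd.Series(keep, index=labels.index, name="keep")
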