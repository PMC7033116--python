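"""Diffusion-map embedding, diffusion pseudotime and trajectory curves.

The tumor lineage (basal tumor -> CSC1 -> CSC2 -> luminal Clu+) is
reconstructed by a diffusion map on highly variable genes: a Gaussian
kernel with per-cell local scaling (distance to the k-th neighbor),
anisotropic density normalization (alpha = 1), symmetrization and
row-normalization to a stochastic operator whose nontrivial right
eigenvectors, scaled by their eigenvalues, give the diffusion
coordinates.  Diffusion pseudotime is the diffusion distance to a root
cell, min-max scaled to [0, 1].  The trajectory curve smooths each
diffusion coordinate over pseudotime with local linear (LOESS)
regression, which also smooths gene expression and module scores along
the path; reproducibility is checked by recomputing pseudotime per
sample, and the early-vs-late stage shift is tested by a linear model
with cluster-robust (by sample) standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryResult",
    "StageShiftResult",
    "diffusion_map",
    "diffusion_pseudotime",
    "fit_trajectory_curve",
    "smooth_over_pseudotime",
    "per_sample_reproducibility",
    "stage_shift_test",
    "neighbor_smooth",
]


@dataclass
class TrajectoryResult:
    """Diffusion embedding plus (once computed) pseudotime and curve."""

    coords: pd.DataFrame  # cells x DC1..DCn, eigenvalue-scaled
    eigenvalues: np.ndarray  # nonincreasing, all < 1 (trivial one dropped)
    psi: np.ndarray  # unscaled right eigenvectors (cells x n_comps)
    pseudotime: pd.Series | None = None
    root_cell: str | None = None
    curve: pd.DataFrame | None = None


@dataclass
class StageShiftResult:
    """Linear-model test of pseudotime on tumor stage."""

    slope: float
    p: float
    n_cells: int
    n_samples: int


def diffusion_map(expr: pd.DataFrame, n_comps: int = 10, k_kernel: int = 15,
                  alpha: float = 1.0,
                  on_disconnected: str = "error") -> TrajectoryResult:
    """Diffusion-map embedding of cells (genes x cells expression).

    Local-scale Gaussian kernel on the union kNN graph, anisotropic
    normalization with exponent ``alpha``, then the row-stochastic
    operator's leading nontrivial eigenvectors.  The trivial eigenvalue
    is verified to be 1 and dropped.  A disconnected kernel graph is an
    error (component sizes reported) unless ``on_disconnected='bridge'``,
    which joins components through their mutually nearest cell pairs —
    useful when an analysis deliberately removes an intermediate
    population and the remaining ends must still be ordered.
    """
    mat = expr.to_numpy(dtype=float).T  # cells x genes
    n = mat.shape[0]
    if n < n_comps + 2:
        raise ValueError(f"need at least {n_comps + 2} cells for "
                         f"{n_comps} components")
    from sklearn.neighbors import NearestNeighbors

    k = min(k_kernel, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(mat)
    dist, idx = nn.kneighbors(mat)
    sigma = dist[:, -1]  # distance to k-th neighbor (local scale)
    sigma = np.maximum(sigma, 1e-12)

    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    d2 = (dist[:, 1:] ** 2).ravel()
    w = np.exp(-d2 / (sigma[rows] * sigma[cols]))
    K = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    K = K.maximum(K.T)  # symmetric union graph
    K = K + sparse.identity(n, format="csr")  # self-transition mass

    n_comp_graph, labels = connected_components(K, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        if on_disconnected != "bridge":
            raise ValueError("kernel graph is disconnected; component sizes: "
                             f"{sorted(sizes.tolist(), reverse=True)}")
        logger.warning("diffusion_map: bridging %d components (sizes %s)",
                       n_comp_graph, sorted(sizes.tolist(), reverse=True))
        K = K.tolil()
        while n_comp_graph > 1:
            # join component 0 to its nearest other component
            a = np.flatnonzero(labels == 0)
            b = np.flatnonzero(labels != 0)
            d = np.linalg.norm(mat[a][:, None, :] - mat[b][None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            ia, jb = a[i], b[j]
            w_bridge = np.exp(-d[i, j] ** 2 / (sigma[ia] * sigma[jb]))
            w_bridge = max(w_bridge, 1e-6)
            K[ia, jb] = K[jb, ia] = w_bridge
            n_comp_graph, labels = connected_components(K.tocsr(),
                                                        directed=False)
        K = K.tocsr()

    # anisotropic normalization K / (q_i^a q_j^a)
    q = np.asarray(K.sum(axis=1)).ravel()
    qa = q ** (-alpha)
    K = sparse.diags(qa) @ K @ sparse.diags(qa)
    d = np.asarray(K.sum(axis=1)).ravel()
    dm = sparse.diags(d ** -0.5)
    S = dm @ K @ dm  # symmetric conjugate of the stochastic operator
    S = (S + S.T) / 2.0

    if n <= 1500:
        evals, evecs = np.linalg.eigh(S.toarray())
        evals, evecs = evals[::-1], evecs[:, ::-1]
    else:
        from scipy.sparse.linalg import eigsh

        evals, evecs = eigsh(S, k=n_comps + 1, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    if abs(evals[0] - 1.0) > 1e-8:
        raise RuntimeError(f"trivial eigenvalue is {evals[0]!r}, expected 1")
    evals = evals[1:n_comps + 1]
    psi = (dm @ evecs[:, 1:n_comps + 1])
    # normalize against the trivial eigenvector so scales are comparable
    phi0 = dm @ evecs[:, [0]]
    psi = psi / np.abs(phi0)
    # sign convention: largest-magnitude entry positive
    s = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    s[s == 0] = 1.0
    psi = psi * s
    coords = psi * evals
    index = expr.columns
    coords = pd.DataFrame(coords, index=index,
                          columns=[f"DC{i + 1}" for i in range(coords.shape[1])])
    return TrajectoryResult(coords=coords, eigenvalues=evals, psi=psi)


def diffusion_pseudotime(result: TrajectoryResult, root_cluster=None,
                         cluster_labels: pd.Series | None = None,
                         root_cell=None, rel_weight_floor: float = 0.01) -> pd.Series:
    """Diffusion distance to a root cell, min-max scaled to [0, 1].

    pseudotime(x) = || (lambda_i / (1 - lambda_i)) (psi_i(x) - psi_i(root)) ||
    over retained components; components whose weight lambda/(1-lambda)
    falls below ``rel_weight_floor`` of the leading one are dropped.
    When a root cluster is given, the root cell is that cluster's
    extreme cell on DC1, which anchors the origin (lowest pseudotime) at
    the designated starting population.
    """
    lam = result.eigenvalues
    if np.any(lam >= 1.0):
        raise ValueError("retained eigenvalue >= 1; cannot weight components")
    weights = lam / (1.0 - lam)
    keep = weights >= rel_weight_floor * weights[0]
    cells = result.coords.index
    if root_cell is None:
        if root_cluster is None or cluster_labels is None:
            raise ValueError("give either root_cell or root_cluster + labels")
        members = cells[(cluster_labels.reindex(cells) == root_cluster).to_numpy()]
        if len(members) == 0:
            raise ValueError(f"root cluster {root_cluster!r} has no cells")
        dc1 = result.coords.loc[members, "DC1"]
        center = result.coords["DC1"].median()
        root_cell = (dc1 - center).abs().idxmax()
    ri = cells.get_loc(root_cell)
    diff = (result.psi[:, keep] - result.psi[ri, keep]) * weights[keep]
    dpt = np.linalg.norm(diff, axis=1)
    rng = dpt.max() - dpt.min()
    if rng > 0:
        dpt = (dpt - dpt.min()) / rng
    pt = pd.Series(dpt, index=cells, name="pseudotime")
    result.pseudotime = pt
    result.root_cell = root_cell
    return pt


def _loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float):
    """First-degree LOESS with tricube weights; returns (fit, se).

    At every evaluation point the span-fraction nearest data points get
    tricube weights and a weighted straight line is fitted; the
    pointwise standard error comes from the equivalent-kernel norm and a
    global residual variance estimate.
    """
    n = len(x)
    r = int(np.ceil(span * n))
    if r < 2 or r > n:
        raise ValueError(f"span {span} leaves {r} points; need 2..{n} "
                         f"(minimum span {2.0 / n:.3f})")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fit = np.empty(len(x_eval))
    se = np.empty(len(x_eval))
    # residual scale from a pilot pass at the data points themselves
    sigma2 = None
    for target, out_fit, out_se in ((xs, None, None), (x_eval, fit, se)):
        fitted = np.empty(len(target))
        l2 = np.empty(len(target))
        for i, x0 in enumerate(target):
            d = np.abs(xs - x0)
            cut = np.partition(d, r - 1)[r - 1]
            cut = max(cut, 1e-12)
            m = d <= cut
            u = d[m] / cut
            w = (1 - u**3) ** 3
            w = np.maximum(w, 1e-12)
            X = np.column_stack([np.ones(m.sum()), xs[m] - x0])
            W = w
            A = X.T @ (X * W[:, None])
            b = X.T @ (W * ys[m])
            try:
                coef = np.linalg.solve(A, b)
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                coef = np.array([np.average(ys[m], weights=W), 0.0])
                Ainv = None
            fitted[i] = coef[0]
            if Ainv is not None:
                lvec = (Ainv @ X.T * W)[0]  # equivalent kernel at x0
                l2[i] = float(lvec @ lvec)
            else:
                l2[i] = float((W / W.sum()) @ (W / W.sum()))
        if out_fit is None:
            resid = ys - fitted
            dof = max(len(xs) - 2, 1)
            sigma2 = float(resid @ resid) / dof
        else:
            out_fit[:] = fitted
            out_se[:] = np.sqrt(sigma2 * l2)
    return fit, se


def smooth_over_pseudotime(values, pseudotime, span: float = 0.5,
                           n_grid: int = 100):
    """LOESS curve of per-cell values over pseudotime with a 95% band.

    Returns a DataFrame with columns pseudotime, fit, lo, hi on an even
    pseudotime grid.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 cells")
    if np.ptp(t) == 0:
        raise ValueError("pseudotime is constant; nothing to smooth over")
    grid = np.linspace(t.min(), t.max(), n_grid)
    fit, se = _loess(t, y, grid, span)
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({"pseudotime": grid, "fit": fit,
                         "lo": fit - z * se, "hi": fit + z * se})


def fit_trajectory_curve(result: TrajectoryResult, span: float = 0.5,
                         n_grid: int = 100) -> pd.DataFrame:
    """Trajectory curve: each diffusion coordinate smoothed over pseudotime.

    Returns the fitted coordinates on an even pseudotime grid, ordered
    by pseudotime.  ``n_grid = 1`` degenerates to a single point at the
    median pseudotime.
    """
    if result.pseudotime is None:
        raise ValueError("compute diffusion_pseudotime first")
    t = result.pseudotime.to_numpy()
    if n_grid == 1:
        grid = np.array([np.median(t)])
    else:
        grid = np.linspace(t.min(), t.max(), n_grid)
    cols = {}
    for name in result.coords.columns:
        fit, _ = _loess(t, result.coords[name].to_numpy(), grid, span)
        cols[name] = fit
    curve = pd.DataFrame({"pseudotime": grid, **cols})
    result.curve = curve
    return curve


def per_sample_reproducibility(expr: pd.DataFrame, metadata: pd.DataFrame,
                               global_pseudotime: pd.Series,
                               root_labels: pd.Series,
                               root_cluster,
                               min_cells: int = 10,
                               n_comps: int = 10,
                               k_kernel: int = 15) -> pd.DataFrame:
    """Per-sample pseudotime vs the global estimate.

    The diffusion map and pseudotime are recomputed on every sample with
    strictly more than ``min_cells`` cells in the relevant populations,
    and compared to the global pseudotime on the shared cells by
    absolute Spearman correlation (sign-aligned).
    """
    rows = []
    for sample, cells in metadata.groupby("sample", observed=True).groups.items():
        cells = pd.Index(cells).intersection(expr.columns)
        if len(cells) <= min_cells:
            continue
        sub = expr[cells]
        try:
            res = diffusion_map(sub, n_comps=min(n_comps, len(cells) - 2),
                                k_kernel=min(k_kernel, len(cells) - 1))
            labs = root_labels.reindex(cells)
            if (labs == root_cluster).any():
                pt = diffusion_pseudotime(res, root_cluster=root_cluster,
                                          cluster_labels=labs)
            else:
                pt = diffusion_pseudotime(res, root_cell=cells[0])
        except (ValueError, RuntimeError) as exc:
            logger.warning("per_sample_reproducibility: sample %s skipped (%s)",
                           sample, exc)
            continue
        rho = stats.spearmanr(pt.to_numpy(),
                              global_pseudotime.reindex(cells).to_numpy())[0]
        rows.append({"sample": sample, "n_cells": len(cells),
                     "abs_spearman": float(abs(rho))})
    if not rows:
        logger.warning("per_sample_reproducibility: no qualifying sample")
        return pd.DataFrame(columns=["sample", "n_cells", "abs_spearman"])
    return pd.DataFrame(rows)


def stage_shift_test(pseudotime: pd.Series, metadata: pd.DataFrame,
                     populations: pd.Series | None = None,
                     relevant_populations=None,
                     min_cells: int = 5,
                     genotype: str | None = "double_mutant") -> StageShiftResult:
    """OLS of pseudotime on stage with cluster-robust (sample) errors.

    Only samples of the tumor genotype with at least ``min_cells`` cells
    in the relevant populations enter.  The slope is the P90 - P40 shift
    in mean pseudotime; its p-value uses standard errors clustered by
    sample, referred to a t distribution with (clusters - 2) degrees of
    freedom — the usual small-sample reference when only a dozen
    clusters carry the design.
    """
    import statsmodels.api as sm

    cells = pseudotime.index
    meta = metadata.loc[cells]
    keep = pd.Series(True, index=cells)
    if genotype is not None and "genotype" in meta:
        keep &= meta["genotype"] == genotype
    if populations is not None and relevant_populations is not None:
        keep &= populations.reindex(cells).isin(relevant_populations)
    sizes = meta.loc[keep, "sample"].value_counts()
    good_samples = sizes.index[sizes >= min_cells]
    keep &= meta["sample"].isin(good_samples)
    sub = meta[keep]
    stages = sorted(sub["stage"].unique())
    if len(stages) < 2:
        raise ValueError(f"only stage(s) {stages} present after filtering")
    y = pseudotime[keep].to_numpy(float)
    x = (sub["stage"] == stages[1]).to_numpy(float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type="cluster",
                           cov_kwds={"groups": sub["sample"].to_numpy()})
    n_samples = int(sub["sample"].nunique())
    tstat = float(fit.params[1] / fit.bse[1])
    p = float(2 * stats.t.sf(abs(tstat), max(n_samples - 2, 1)))
    return StageShiftResult(slope=float(fit.params[1]), p=p,
                            n_cells=int(keep.sum()),
                            n_samples=n_samples)


def neighbor_smooth(expr: pd.DataFrame, k: int = 0,
                    neighbors: np.ndarray | None = None) -> pd.DataFrame:
    """kNN-average expression smoothing.

    A simple synthetic-data-friendly smoother: each cell's expression is
    replaced by the mean over itself and its k nearest neighbors
    (computed on the expression matrix when not supplied).  ``k = 0`` is
    the identity.  Off by default in the pipeline.
    """
    if k == 0:
        return expr.copy()
    from .mixing import knn_graph

    mat = expr.to_numpy(dtype=float)
    if neighbors is None:
        neighbors = knn_graph(mat.T, k)
    n = mat.shape[1]
    out = mat.copy()
    for i in range(n):
        out[:, i] = (mat[:, i] + mat[:, neighbors[i]].sum(axis=1)) / (k + 1)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
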