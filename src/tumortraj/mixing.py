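"""Entropy-based sample-mixing QC.

Quantifies how well each cell's local neighborhood reflects the global
sample composition using the Kullback-Leibler divergence

    D_j = sum_i q_i * log(q_i / q_i^0)        (natural log, nats)

where q_i is the proportion of cells from group i among the k nearest
neighbors N(j) of cell j (kNN in PCA space), and q_i^0 the global
proportion of group i.  D_j = 0 means the neighborhood mirrors the
dataset; the maximum ln(1/q_i^0) is attained by a pure neighborhood of
the rarest group.  A permutation null (random relabeling of cells) gives
the expected mixing under exchangeability, and a chain-rule
decomposition splits replicate-level divergence into a biological-factor
component and a residual within-factor (replicate) component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixingResult",
    "knn_graph",
    "mixing_divergence",
    "shuffle_null",
    "decompose_mixing",
]


@dataclass
class MixingResult:
    """Per-cell KL divergence of neighborhood vs global composition."""

    divergence: pd.Series  # D_j per cell, in nats
    groups: pd.Index  # group levels I
    q0: np.ndarray  # global proportions per group
    k: int


def knn_graph(pca_coords, k: int) -> np.ndarray:
    """Indices (cells x k) of each cell's k nearest Euclidean neighbors.

    Self is excluded; distance ties are broken by cell index, so the
    result is fully deterministic.
    """
    coords = np.asarray(pca_coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    out = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = np.linalg.norm(coords[start:stop, None, :] - coords[None, :, :], axis=2)
        for r, i in enumerate(range(start, stop)):
            d[r, i] = np.inf
        # argsort is stable -> ties resolved by index
        out[start:stop] = np.argsort(d, axis=1, kind="stable")[:, :k]
    return out


def _kl_rows(q: np.ndarray, q0: np.ndarray) -> np.ndarray:
    """Row-wise KL(q || q0) with the 0*log(0) := 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q / q0), 0.0)
    return terms.sum(axis=1)


def _profiles(neighbors: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Neighborhood composition q (cells x groups)."""
    n, k = neighbors.shape
    counts = np.zeros((n, n_groups))
    neigh_codes = codes[neighbors]
    for g in range(n_groups):
        counts[:, g] = (neigh_codes == g).sum(axis=1)
    return counts / k


def mixing_divergence(neighbors: np.ndarray, labels,
                      q0: pd.Series | None = None) -> MixingResult:
    """Per-cell KL divergence of neighborhood vs global group composition.

    ``q0`` defaults to the empirical global proportions; when supplied it
    must cover every observed label with positive mass.
    """
    labels = pd.Series(labels).astype("category") if not isinstance(
        labels, pd.Series) else labels.astype("category")
    cats = labels.cat.categories
    codes = labels.cat.codes.to_numpy()
    if (codes < 0).any():
        raise ValueError("labels contain missing values")
    if q0 is None:
        q0_vec = np.bincount(codes, minlength=len(cats)) / len(codes)
    else:
        missing = [c for c in cats if c not in q0.index or q0[c] <= 0]
        if missing:
            raise ValueError(f"labels absent from q0 or non-positive: {missing}")
        q0_vec = np.asarray([q0[c] for c in cats], dtype=float)
        q0_vec = q0_vec / q0_vec.sum()
    q = _profiles(neighbors, codes, len(cats))
    d = _kl_rows(q, q0_vec)
    index = labels.index
    return MixingResult(divergence=pd.Series(d, index=index, name="D"),
                        groups=pd.Index(cats), q0=q0_vec, k=neighbors.shape[1])


def shuffle_null(neighbors: np.ndarray, labels, n_perm: int = 100,
                 seed: int = 0):
    """Permutation null of the mean divergence under random relabeling.

    Group assignments are shuffled uniformly across cells; D is
    recomputed against the unchanged global proportions.  Returns a dict
    with the observed mean, the permuted means, and a one-sided
    empirical p-value for the observed mean exceeding the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = pd.Series(labels).astype("category") if not isinstance(
        labels, pd.Series) else labels.astype("category")
    codes = labels.cat.codes.to_numpy()
    n_groups = len(labels.cat.categories)
    q0 = np.bincount(codes, minlength=n_groups) / len(codes)
    obs = _kl_rows(_profiles(neighbors, codes, n_groups), q0).mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(codes)
        null[p] = _kl_rows(_profiles(neighbors, perm, n_groups), q0).mean()
    p_value = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return {"observed_mean": float(obs), "null_means": null, "p_value": p_value}


def expected_null_divergence(n_groups: int, k: int) -> float:
    """Chi-square approximation to the mean D under i.i.d. labels."""
    return (n_groups - 1) / (2.0 * k)


def decompose_mixing(neighbors: np.ndarray, replicate_labels,
                     factor_map: dict) -> pd.DataFrame:
    """Chain-rule split of replicate-level divergence.

    Replicates nest in biological groups via ``factor_map`` (replicate ->
    group).  For every cell,

        D_total = D_between + sum_b q_b * D_within(b),

    exactly: D_total is the replicate-level KL, D_between the KL after
    aggregating profiles by biological group, and D_within(b) the KL of
    the conditional within-group replicate profile against its global
    conditional.  Returns a per-cell frame with columns D_total,
    D_between, D_within (the weighted sum), and carries the summary
    fraction mean(D_between)/mean(D_total) in ``attrs['fraction_between']``.
    """
    labels = pd.Series(replicate_labels).astype("category") if not isinstance(
        replicate_labels, pd.Series) else replicate_labels.astype("category")
    reps = list(labels.cat.categories)
    missing = [r for r in reps if r not in factor_map]
    if missing:
        raise ValueError(f"replicates missing from factor_map: {missing}")
    codes = labels.cat.codes.to_numpy()
    n_reps = len(reps)
    q_rep = _profiles(neighbors, codes, n_reps)
    q0_rep = np.bincount(codes, minlength=n_reps) / len(codes)

    groups = sorted({factor_map[r] for r in reps}, key=str)
    g_of_rep = np.array([groups.index(factor_map[r]) for r in reps])
    agg = np.zeros((n_reps, len(groups)))
    agg[np.arange(n_reps), g_of_rep] = 1.0
    q_grp = q_rep @ agg
    q0_grp = q0_rep @ agg

    d_total = _kl_rows(q_rep, q0_rep)
    d_between = _kl_rows(q_grp, q0_grp)

    d_within = np.zeros(len(q_rep))
    for b in range(len(groups)):
        members = np.flatnonzero(g_of_rep == b)
        qb = q_grp[:, b]
        q0b = q0_grp[b]
        pos = qb > 0
        if not pos.any():
            continue
        cond = q_rep[np.ix_(pos, members)] / qb[pos, None]
        cond0 = q0_rep[members] / q0b
        d_within[pos] += qb[pos] * _kl_rows(cond, cond0)

    out = pd.DataFrame({"D_total": d_total, "D_between": d_between,
                        "D_within": d_within}, index=labels.index)
    mt = d_total.mean()
    out.attrs["fraction_between"] = float(d_between.mean() / mt) if mt > 0 else np.nan
    return out
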