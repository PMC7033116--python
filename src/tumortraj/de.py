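"""Pseudobulk differential expression and cell-composition testing.

Single-cell counts are pooled per (sample, group) into pseudobulk
columns so replicate-level count models apply.  Genes are tested with
negative-binomial log-linear models: a Wald test on a two-level contrast
with centered log10 cell count as covariate, or a likelihood-ratio test
across the four trajectory populations.  Composition shifts are tested
with a binomial random-intercept (per-sample) model fitted by
Gauss-Hermite marginal likelihood, with a beta-binomial ML fallback.
Size factors follow the median-of-ratios convention, and a bulk-vs-
pooled-profile Pearson correlation (TPM-scale, genes above a detection
floor in all compared samples) closes the loop with bulk RNA-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkTable",
    "DEResult",
    "aggregate_pseudobulk",
    "size_factors",
    "expression_fraction_filter",
    "nb_wald_test",
    "nb_lrt_test",
    "composition_test",
    "pooled_vs_bulk_correlation",
    "bh_adjust",
]


@dataclass
class PseudobulkTable:
    """Pooled counts per (sample, group) with design and cell counts."""

    counts: pd.DataFrame  # genes x columns, integer
    n_cells: pd.Series  # per column
    design: pd.DataFrame  # per column: sample, group + sample-level factors


def aggregate_pseudobulk(counts: pd.DataFrame, metadata: pd.DataFrame,
                         group_field: str) -> PseudobulkTable:
    """Sum single-cell counts over (sample, group); empty columns dropped."""
    if group_field not in metadata.columns:
        raise ValueError(f"metadata lacks column {group_field!r}")
    meta = metadata.loc[counts.columns]
    key = meta["sample"].astype(str) + "|" + meta[group_field].astype(str)
    codes, cols = pd.factorize(key, sort=True)
    mat = counts.to_numpy()
    pooled = np.zeros((mat.shape[0], len(cols)), dtype=np.int64)
    for c in range(len(cols)):
        pooled[:, c] = mat[:, codes == c].sum(axis=1)
    n_cells = pd.Series(np.bincount(codes, minlength=len(cols)), index=cols,
                        name="n_cells")
    design_rows = []
    extra = [c for c in ("genotype", "sex", "stage") if c in meta.columns]
    for col in cols:
        sample, group = col.split("|", 1)
        sub = meta[key == col].iloc[0]
        design_rows.append({"column": col, "sample": sample, "group": group,
                            **{c: sub[c] for c in extra}})
    design = pd.DataFrame(design_rows).set_index("column")
    table = pd.DataFrame(pooled, index=counts.index, columns=cols)
    return PseudobulkTable(counts=table, n_cells=n_cells, design=design)


def size_factors(pooled: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean 1.

    Uses genes with nonzero counts in every column; if none exist,
    falls back to total-count factors (logged).
    """
    mat = pooled.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logmat = np.log(mat[all_pos])
        logref = logmat.mean(axis=1, keepdims=True)
        logfac = np.median(logmat - logref, axis=0)
    else:
        logger.warning("size_factors: no gene nonzero in all columns; "
                       "falling back to total-count factors")
        totals = mat.sum(axis=0)
        logfac = np.log(totals)
    logfac = logfac - logfac.mean()
    return pd.Series(np.exp(logfac), index=pooled.columns, name="size_factor")


def expression_fraction_filter(counts: pd.DataFrame, cell_subset=None,
                               min_frac: float = 0.05) -> pd.Series:
    """Genes nonzero in at least ``min_frac`` of the subset's cells."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    sub = counts if cell_subset is None else counts.loc[:, cell_subset]
    if sub.shape[1] == 0:
        raise ValueError("cell subset is empty")
    frac = (sub.to_numpy() > 0).mean(axis=1)
    return pd.Series(frac >= min_frac, index=counts.index, name="keep")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# --- negative-binomial GLM machinery ---------------------------------------

def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood (var = mu + alpha mu^2)."""
    if alpha < 1e-10:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    return float(np.sum(special.gammaln(y + r) - special.gammaln(r)
                        - special.gammaln(y + 1) + r * np.log(r / (r + mu))
                        + y * np.log(mu / (r + mu))))


def _nb_irls(y, X, offset, alpha, beta0=None, max_iter=50, tol=1e-8):
    """Fisher-scoring fit of an NB2 log-linear model; returns (beta, mu, cov)."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()
    else:
        beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        WX = X * w[:, None]
        try:
            xtwx = X.T @ WX
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(beta_new)):
            return None
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
    except np.linalg.LinAlgError:
        return None
    return beta, mu, cov


def _estimate_alpha(y, mu, n_params, method="pearson"):
    """Per-gene NB dispersion at fixed fitted means.

    ``pearson`` (default) solves sum((y-mu)^2 / (mu + alpha mu^2)) =
    n - p, i.e. matches the Pearson chi-square to its residual degrees
    of freedom — the degree-of-freedom adjustment keeps small-sample
    Wald tests close to nominal.  ``ml`` maximizes the NB likelihood in
    alpha; it is smaller in expectation at pseudobulk sample sizes and
    is kept as an option (with the Pearson value as fallback).
    """
    n = len(y)
    resid2 = (y - mu) ** 2
    dof = max(n - n_params, 1)

    def pearson(alpha):
        return float(np.sum(resid2 / (mu + alpha * mu**2))) - dof

    lo, hi = 1e-8, 100.0
    if pearson(lo) <= 0:
        mom = lo
    elif pearson(hi) >= 0:
        mom = hi
    else:
        mom = optimize.brentq(pearson, lo, hi, xtol=1e-8)
    if method == "pearson":
        return float(mom)

    def nll(log_alpha):
        return -_nb_loglik(y, mu, np.exp(log_alpha))

    try:
        res = optimize.minimize_scalar(
            nll, bounds=(np.log(1e-8), np.log(100.0)), method="bounded",
            options={"xatol": 1e-4})
        if res.success and np.isfinite(res.fun):
            return float(np.exp(res.x))
    except Exception:  # pragma: no cover - numeric edge
        pass
    return float(mom)


def _fit_gene_nb(y, X, offset, n_alpha_rounds=2, alpha_method="pearson"):
    """Alternate beta (IRLS) and alpha updates; None if non-convergent."""
    fit = _nb_irls(y, X, offset, alpha=1e-8)
    if fit is None:
        return None
    beta, mu, _ = fit
    alpha = _estimate_alpha(y, mu, X.shape[1], alpha_method)
    for _ in range(n_alpha_rounds):
        fit = _nb_irls(y, X, offset, alpha, beta0=beta)
        if fit is None:
            return None
        beta, mu, cov = fit
        alpha = _estimate_alpha(y, mu, X.shape[1], alpha_method)
    fit = _nb_irls(y, X, offset, alpha, beta0=beta)
    if fit is None:
        return None
    beta, mu, cov = fit
    ll = _nb_loglik(y, mu, alpha)
    return {"beta": beta, "mu": mu, "cov": cov, "alpha": alpha, "loglik": ll}


def _design_matrix(design: pd.DataFrame, contrast_field: str | None,
                   n_cells: pd.Series, covariates: tuple = ()):
    """Intercept + contrast indicator + centered log10 cell count (+ extras)."""
    cols = ["intercept"]
    X = [np.ones(len(design))]
    contrast_idx = None
    if contrast_field is not None:
        levels = sorted(design[contrast_field].unique(), key=str)
        if len(levels) != 2:
            raise ValueError(
                f"contrast field {contrast_field!r} must have 2 levels, "
                f"got {levels}")
        X.append((design[contrast_field] == levels[1]).to_numpy(float))
        cols.append(f"{contrast_field}[{levels[1]}]")
        contrast_idx = len(cols) - 1
    lc = np.log10(n_cells.loc[design.index].to_numpy(float))
    if lc.std() > 0:  # constant cell counts carry no information
        X.append(lc - lc.mean())
        cols.append("log10_n_cells")
    for cov in covariates:
        lv = sorted(design[cov].unique(), key=str)
        for level in lv[1:]:
            X.append((design[cov] == level).to_numpy(float))
            cols.append(f"{cov}[{level}]")
    return np.column_stack(X), cols, contrast_idx


def nb_wald_test(pseudobulk: PseudobulkTable, contrast_field: str,
                 covariates: tuple = (), min_count: int = 1,
                 use_t: bool = True) -> pd.DataFrame:
    """Per-gene NB Wald test of a two-level contrast on pseudobulk.

    The model is log mu = X beta + log(size factor), with centered
    log10(cell count) always included as covariate.  The Wald statistic
    on the contrast coefficient is referred to a t distribution with
    (columns - parameters) degrees of freedom (``use_t=False`` for the
    asymptotic normal).  All-zero (or near-zero) genes are excluded
    before fitting; non-convergent genes get p = NA and do not enter the
    BH denominator.  Log2 fold changes are natural-log coefficients
    rescaled to base 2.
    """
    table, design = pseudobulk.counts, pseudobulk.design
    for level in design[contrast_field].unique():
        if (design[contrast_field] == level).sum() < 2:
            raise ValueError(f"contrast level {level!r} has fewer than 2 columns")
    X, cols, ci = _design_matrix(design, contrast_field, pseudobulk.n_cells,
                                 covariates)
    sf = size_factors(table)
    offset = np.log(sf.to_numpy())
    mat = table.to_numpy(dtype=float)
    tested = mat.sum(axis=1) >= min_count
    n, p = X.shape
    df_resid = max(n - p, 1)

    out = pd.DataFrame(index=table.index, columns=[
        "log2fc", "se", "stat", "p", "q", "alpha", "status"])
    out["status"] = "not_tested"
    ln2 = np.log(2.0)
    n_fail = 0
    for g in np.flatnonzero(tested):
        fit = _fit_gene_nb(mat[g], X, offset)
        if fit is None:
            out.iloc[g, out.columns.get_loc("status")] = "failed"
            n_fail += 1
            continue
        b = fit["beta"][ci]
        se = float(np.sqrt(fit["cov"][ci, ci]))
        stat = b / se if se > 0 else np.nan
        if use_t:
            pval = 2 * stats.t.sf(abs(stat), df_resid)
        else:
            pval = 2 * stats.norm.sf(abs(stat))
        out.iloc[g] = [b / ln2, se / ln2, stat, pval, np.nan,
                       fit["alpha"], "ok"]
    if n_fail:
        logger.warning("nb_wald_test: %d genes failed to converge", n_fail)
    out["q"] = bh_adjust(out["p"].to_numpy(float))
    out.attrs["test"] = "Wald"
    out.attrs["n_failed"] = n_fail
    return out


def nb_lrt_test(pseudobulk: PseudobulkTable, group_field: str = "group",
                covariates: tuple = (), min_count: int = 1) -> pd.DataFrame:
    """NB likelihood-ratio test across all groups simultaneously.

    Full model: intercept + group factor + centered log10 cell count;
    reduced model drops the group factor.  The statistic is twice the
    log-likelihood difference; divided by its (groups - 1) degrees of
    freedom it is referred to an F distribution with (columns - full
    parameters) denominator degrees of freedom — the finite-sample
    version of the chi-square reference, which it approaches as the
    number of pseudobulk columns grows.  Supports ranking the top
    differential genes along the trajectory.
    """
    table, design = pseudobulk.counts, pseudobulk.design
    levels = sorted(design[group_field].unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups for an LRT")
    big_enough = sum((design[group_field] == lv).sum() >= 2 for lv in levels)
    if big_enough < 2:
        raise ValueError("need >= 2 columns in >= 2 groups")
    # full design: group indicators
    X_red, _, _ = _design_matrix(design, None, pseudobulk.n_cells, covariates)
    ind = np.column_stack([(design[group_field] == lv).to_numpy(float)
                           for lv in levels[1:]])
    X_full = np.column_stack([X_red, ind])
    df = len(levels) - 1
    sf = size_factors(table)
    offset = np.log(sf.to_numpy())
    mat = table.to_numpy(dtype=float)
    tested = mat.sum(axis=1) >= min_count

    out = pd.DataFrame(index=table.index,
                       columns=["stat", "p", "q", "alpha", "status"])
    out["status"] = "not_tested"
    n_fail = 0
    for g in np.flatnonzero(tested):
        full = _fit_gene_nb(mat[g], X_full, offset)
        if full is None:
            out.iloc[g, out.columns.get_loc("status")] = "failed"
            n_fail += 1
            continue
        red = _nb_irls(mat[g], X_red, offset, full["alpha"])
        if red is None:
            out.iloc[g, out.columns.get_loc("status")] = "failed"
            n_fail += 1
            continue
        ll_red = _nb_loglik(mat[g], red[1], full["alpha"])
        stat = max(0.0, 2.0 * (full["loglik"] - ll_red))
        pval = stats.f.sf(stat / df, df, max(len(mat[g]) - X_full.shape[1], 1))
        out.iloc[g] = [stat, pval, np.nan, full["alpha"], "ok"]
    if n_fail:
        logger.warning("nb_lrt_test: %d genes failed to converge", n_fail)
    out["q"] = bh_adjust(out["p"].to_numpy(float))
    out.attrs["test"] = "LRT"
    out.attrs["n_failed"] = n_fail
    return out


# --- composition testing ----------------------------------------------------

def _binomial_glmm_nll(params, y, n, X, nodes, weights):
    """Negative marginal log-likelihood of a binomial random-intercept model.

    Per-sample 1D integrals over the random intercept are evaluated with
    Gauss-Hermite quadrature (nodes/weights pre-scaled for N(0,1)).
    """
    k = X.shape[1]
    beta, log_sigma = params[:k], params[k]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    # eta: samples x nodes
    eta = eta0[:, None] + sigma * nodes[None, :]
    # binomial loglik up to the constant choose(n, y)
    ll = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    m = ll.max(axis=1, keepdims=True)
    integ = np.log(np.exp(ll - m) @ weights) + m[:, 0]
    return -float(integ.sum())


def _binomial_glmm_nll_reml(params, y, n, X, nodes, weights):
    """REML-penalized objective: ML underestimates the random-intercept
    variance at a few dozen samples; the penalty 0.5 log|X' W_eff X| uses
    the effective per-sample information 1/(1/(n p (1-p)) + sigma^2)."""
    base = _binomial_glmm_nll(params, y, n, X, nodes, weights)
    k = X.shape[1]
    beta, sigma = params[:k], np.exp(params[k])
    p = special.expit(X @ beta)
    w = np.maximum(n * p * (1 - p), 1e-8)
    eff = 1.0 / (1.0 / w + sigma**2)
    _, logdet = np.linalg.slogdet((X * eff[:, None]).T @ X)
    return base + 0.5 * logdet


def composition_test(comp_table: pd.DataFrame, cluster: str,
                     sample_design: pd.DataFrame,
                     fixed_effects: tuple = ("genotype", "sex", "stage"),
                     n_quad: int = 25) -> pd.DataFrame:
    """Mixed-effects binomial test of cluster membership proportions.

    ``comp_table`` is samples x clusters (integer cell counts); the
    response is cells in ``cluster`` vs all other cells, with a logit
    link, the requested sample-level fixed effects and a random
    intercept per sample, fitted by Gauss-Hermite marginal maximum
    likelihood with an approximate REML penalty on the variance
    component.  Returns per-fixed-effect log-odds estimates, SEs and
    Wald p-values referred to a t distribution with (samples -
    parameters) degrees of freedom — the small-sample version of the
    asymptotic normal.  If the mixed fit fails, a beta-binomial ML fit with
    the sample as overdispersion unit is used (status column says so).
    Complete separation (cluster confined to one design cell) is
    flagged with p = NA.
    """
    if cluster not in comp_table.columns:
        raise ValueError(f"cluster {cluster!r} not in composition table")
    y = comp_table[cluster].to_numpy(float)
    n = comp_table.sum(axis=1).to_numpy(float)
    design = sample_design.loc[comp_table.index]
    X_cols = ["intercept"]
    X = [np.ones(len(design))]
    for f in fixed_effects:
        levels = sorted(design[f].unique(), key=str)
        if len(levels) < 2:
            continue
        for level in levels[1:]:
            if (design[f] == level).sum() < 3 or (design[f] != level).sum() < 3:
                raise ValueError(
                    f"fewer than 3 samples in a level of fixed effect {f!r}")
            X.append((design[f] == level).to_numpy(float))
            X_cols.append(f"{f}[{level}]")
    X = np.column_stack(X)

    # separation: all member cells in one level of a fixed effect
    separated = set()
    present = y > 0
    for j, name in enumerate(X_cols[1:], start=1):
        lev = X[:, j] > 0.5
        if present.any() and (present[lev].sum() == 0 or present[~lev].sum() == 0):
            separated.add(name)

    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = gh_w / np.sqrt(2 * np.pi)

    k = X.shape[1]
    p0 = max(y.sum() / n.sum(), 1e-6)
    x0 = np.zeros(k + 1)
    x0[0] = np.log(p0 / (1 - p0))
    x0[k] = np.log(0.5)
    status = "glmm"
    try:
        res = optimize.minimize(
            _binomial_glmm_nll_reml, x0, args=(y, n, X, gh_x, weights),
            method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError("non-finite estimates")
        from statsmodels.tools.numdiff import approx_hess

        hess = approx_hess(res.x, _binomial_glmm_nll_reml,
                           args=(y, n, X, gh_x, weights))
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0, np.inf))
        beta = res.x[:k]
        sigma = float(np.exp(res.x[k]))
        if not res.success and not np.all(np.isfinite(se)):
            raise RuntimeError("mixed fit failed")
    except Exception as exc:
        logger.warning("composition_test: mixed fit failed (%s); "
                       "using beta-binomial fallback", exc)
        status = "betabinom"
        beta, se, sigma = _betabinom_fit(y, n, X)

    df_t = max(len(y) - k, 1)
    rows = []
    for j, name in enumerate(X_cols):
        est, s = float(beta[j]), float(se[j])
        if name in separated or not np.isfinite(s) or s == 0:
            pv, flag = np.nan, "separation" if name in separated else "unstable"
        else:
            pv = 2 * stats.t.sf(abs(est / s), df_t)
            flag = status
        rows.append({"term": name, "estimate": est, "se": s, "p": pv,
                     "status": flag})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["sigma"] = sigma
    out.attrs["cluster"] = cluster
    return out


def _betabinom_fit(y, n, X):
    """Beta-binomial ML with logit-linear mean; sample = overdispersion unit."""
    k = X.shape[1]

    def nll(params):
        beta, log_rho = params[:k], params[k]
        rho = np.exp(log_rho) / (1 + np.exp(log_rho))  # in (0,1)
        mu = special.expit(X @ beta)
        conc = (1 - rho) / max(rho, 1e-8)
        a = np.clip(mu * conc, 1e-8, 1e8)
        b = np.clip((1 - mu) * conc, 1e-8, 1e8)
        return -float(np.sum(stats.betabinom.logpmf(y.astype(int),
                                                    n.astype(int), a, b)))

    p0 = max(y.sum() / n.sum(), 1e-6)
    x0 = np.zeros(k + 1)
    x0[0] = np.log(p0 / (1 - p0))
    x0[k] = -3.0
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "fatol": 1e-8})
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    rho = float(special.expit(res.x[k]))
    return res.x[:k], se, rho


def pooled_vs_bulk_correlation(pooled_counts: pd.DataFrame,
                               bulk_tpm: pd.DataFrame,
                               tpm_floor: float = 1e-4) -> pd.DataFrame:
    """Pearson R (log10 scale) between pooled single-cell and bulk profiles.

    Pooled single-cell counts are rescaled to a per-million (TPM-like)
    scale; genes are kept iff strictly above ``tpm_floor`` in every
    compared sample.  Returns one row per (pooled column, bulk column).
    """
    shared = pooled_counts.index.intersection(bulk_tpm.index)
    sc = pooled_counts.loc[shared].to_numpy(float)
    sc = sc / sc.sum(axis=0, keepdims=True) * 1e6
    bk = bulk_tpm.loc[shared].to_numpy(float)
    rows = []
    for i, sc_name in enumerate(pooled_counts.columns):
        for j, bk_name in enumerate(bulk_tpm.columns):
            keep = (sc[:, i] > tpm_floor) & (bk[:, j] > tpm_floor)
            n_genes = int(keep.sum())
            if n_genes < 50:
                logger.warning("pooled_vs_bulk_correlation: only %d genes pass "
                               "the floor for %s vs %s", n_genes, sc_name, bk_name)
            if n_genes >= 3:
                r = float(np.corrcoef(np.log10(sc[keep, i]),
                                      np.log10(bk[keep, j]))[0, 1])
            else:
                r = np.nan
            rows.append({"pooled": sc_name, "bulk": bk_name, "R": r,
                         "n_genes": n_genes})
    return pd.DataFrame(rows)
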