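"""Gene-set enrichment on fold changes and per-cell module scores.

Enrichment of a gene set in a differential-expression result is tested
as an unequal-variance two-sample t-test of member vs non-member log2
fold changes (two-sided; direction given by the sign of the member
mean).  Reported sets are filtered on BH q-value, absolute mean log2
fold change, and the fraction of ribosomal members.  Per-cell module
scores (EMT, Wnt, stemness, ...) are the set-average expression minus
the average of expression-bin-matched control genes, computed on
normalized (optionally neighbor-smoothed) expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "STEMNESS_GENES",
    "GeneSetResult",
    "set_enrichment_test",
    "filter_enrichment",
    "module_score",
    "read_gmt",
    "write_gmt",
    "match_symbols",
]

#: Literature-curated stemness markers (14 mouse symbols, fixed).
#: "Aldh1a" is not a unique mouse symbol (Aldh1a1/2/3 exist); it is kept
#: verbatim and matched by prefix, see :func:`match_symbols`.
STEMNESS_GENES = (
    "Pou5f1", "Nanog", "Sox2", "Prom1", "Bmi1", "Lgr5", "Msi1",
    "Tdgf1", "Bmp4", "Cspg4", "Cxcr4", "Alcam", "Slc2a13", "Aldh1a",
)


@dataclass
class GeneSetResult:
    """Enrichment summary for one gene set."""

    name: str
    mean_lfc: float
    t_stat: float
    p: float
    q: float
    frac_ribosomal: float
    n_members: int


def match_symbols(symbols, universe: pd.Index) -> pd.Index:
    """Resolve gene symbols against a universe; ambiguous names by prefix.

    Symbols absent from the universe are retried as prefixes (e.g.
    "Aldh1a" matches Aldh1a1/2/3); prefix hits are logged.
    """
    hits = []
    for s in symbols:
        if s in universe:
            hits.append(s)
            continue
        pref = [g for g in universe if str(g).startswith(s)]
        if pref:
            logger.info("match_symbols: %r matched by prefix: %s", s, pref)
            hits.extend(pref)
    return pd.Index(pd.unique(pd.Series(hits, dtype=object)))


def set_enrichment_test(lfc: pd.Series, gene_sets: dict,
                        ribo_flags: pd.Series | None = None,
                        min_members: int = 3) -> pd.DataFrame:
    """Welch t-test of member vs non-member log2 fold changes per set.

    ``lfc`` is indexed by gene over the tested background (genes passing
    the expression filter).  Sets with fewer than ``min_members``
    expressed members are skipped (logged).  BH adjustment across tested
    sets.
    """
    lfc = lfc.dropna()
    universe = lfc.index
    rows = []
    for name, genes in gene_sets.items():
        members = match_symbols(genes, universe)
        if len(members) < min_members:
            logger.info("set_enrichment_test: set %r skipped "
                        "(%d expressed members)", name, len(members))
            continue
        in_set = lfc.loc[members].to_numpy(float)
        out_set = lfc.drop(members).to_numpy(float)
        if len(out_set) < 2:
            logger.info("set_enrichment_test: set %r skipped (no background)",
                        name)
            continue
        t, p = stats.ttest_ind(in_set, out_set, equal_var=False)
        ribo = np.nan
        if ribo_flags is not None:
            flags = ribo_flags.reindex(members).fillna(False).astype(bool)
            ribo = float(flags.mean())
        rows.append({"set": name, "mean_lfc": float(in_set.mean()),
                     "t_stat": float(t), "p": float(p),
                     "frac_ribosomal": ribo, "n_members": len(members)})
    out = pd.DataFrame(rows, columns=["set", "mean_lfc", "t_stat", "p",
                                      "frac_ribosomal", "n_members"])
    if len(out):
        out = out.set_index("set")
        from .de import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def filter_enrichment(results: pd.DataFrame, q_max: float = 0.1,
                      min_abs_mean_lfc: float = 0.5,
                      ribo_frac_max: float = 0.1) -> pd.DataFrame:
    """Reporting filter: q < q_max, |mean LFC| strictly > min, and at
    most ``ribo_frac_max`` ribosomal members (strictly more excludes)."""
    if "frac_ribosomal" not in results.columns:
        raise ValueError("results lack the frac_ribosomal column")
    keep = ((results["q"] < q_max)
            & (results["mean_lfc"].abs() > min_abs_mean_lfc)
            & ~(results["frac_ribosomal"] > ribo_frac_max))
    return results[keep]


def module_score(expr: pd.DataFrame, gene_set, n_bins: int = 25,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Per-cell module score: set mean minus bin-matched control mean.

    Genes are binned into ``n_bins`` by dataset-average expression; for
    each set gene ``n_ctrl`` control genes are drawn from its bin
    (without replacement when the bin is large enough, with replacement
    otherwise).  The score is the mean expression of set genes minus the
    mean over the pooled controls, per cell.  Seeded and deterministic.
    """
    members = match_symbols(gene_set, expr.index)
    if len(members) == 0:
        raise ValueError("gene set has no genes present in the expression matrix")
    mean_expr = expr.mean(axis=1)
    # all-zero genes are excluded from binning and from the control pool,
    # so padding the matrix with silent genes cannot change the score
    expressed = mean_expr.index[mean_expr > 0]
    ranks = mean_expr.loc[expressed].rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(ranks)), labels=False,
                   duplicates="drop")
    rng = np.random.default_rng(seed)
    ctrl_genes = []
    member_set = set(members)
    for g in members:
        g_bin = bins[g] if g in bins.index else bins.min()
        pool = bins.index[(bins == g_bin) & ~bins.index.isin(member_set)]
        if len(pool) == 0:
            pool = bins.index[bins == g_bin]
        replace = len(pool) < n_ctrl
        ctrl_genes.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_genes)
    score = (expr.loc[members].mean(axis=0).to_numpy()
             - expr.loc[ctrl].mean(axis=0).to_numpy())
    return pd.Series(score, index=expr.columns, name="score")


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = tuple(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
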