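"""Pseudobulk construction, NB testing, composition model, bulk correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from tumortraj import de as de_mod
from tumortraj.de import PseudobulkTable


# --- pseudobulk aggregation -------------------------------------------------

def _tiny_cells():
    counts = pd.DataFrame({"cA1": [1, 2], "cA2": [0, 3], "cB1": [5, 1]},
                          index=["g1", "g2"])
    meta = pd.DataFrame({"sample": ["s1", "s1", "s1"],
                         "cluster": ["A", "A", "B"],
                         "genotype": ["control"] * 3},
                        index=counts.columns)
    return counts, meta


def test_aggregate_sums_and_conserves():
    counts, meta = _tiny_cells()
    pb = de_mod.aggregate_pseudobulk(counts, meta, "cluster")
    assert list(pb.counts["s1|A"]) == [1, 5]
    assert pb.counts.to_numpy().sum() == counts.to_numpy().sum()
    assert pb.n_cells["s1|A"] == 2


def test_aggregate_order_invariant():
    counts, meta = _tiny_cells()
    perm = ["cB1", "cA2", "cA1"]
    pb1 = de_mod.aggregate_pseudobulk(counts, meta, "cluster")
    pb2 = de_mod.aggregate_pseudobulk(counts[perm], meta.loc[perm], "cluster")
    assert pb1.counts.equals(pb2.counts)


def test_aggregate_missing_field():
    counts, meta = _tiny_cells()
    with pytest.raises(ValueError, match="nope"):
        de_mod.aggregate_pseudobulk(counts, meta, "nope")


# --- size factors -----------------------------------------------------------

def test_size_factors_identical_columns():
    pooled = pd.DataFrame({"a": [10, 5, 2], "b": [10, 5, 2]})
    sf = de_mod.size_factors(pooled)
    assert np.allclose(sf, 1.0)


def test_size_factors_doubled_column():
    pooled = pd.DataFrame({"a": [10, 4, 6], "b": [20, 8, 12]})
    sf = de_mod.size_factors(pooled)
    assert np.isclose(sf["b"] / sf["a"], 2.0)
    # scaling all counts leaves the (normalized) factors unchanged
    sf5 = de_mod.size_factors(pooled * 5)
    assert np.allclose(sf, sf5)


def test_size_factors_fallback_logged(caplog):
    pooled = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
    with caplog.at_level("WARNING"):
        sf = de_mod.size_factors(pooled)
    assert "total-count" in caplog.text
    assert np.allclose(sf, 1.0)  # equal totals


# --- expression fraction filter ---------------------------------------------

@pytest.mark.parametrize("n_pos,kept", [(5, True), (4, False)])
def test_fraction_filter_boundary(n_pos, kept):
    """'At least 5% of cells' is inclusive at exactly 5%."""
    mat = np.zeros((1, 100), dtype=int)
    mat[0, :n_pos] = 3
    counts = pd.DataFrame(mat, index=["g"])
    keep = de_mod.expression_fraction_filter(counts, min_frac=0.05)
    assert bool(keep["g"]) is kept


def test_fraction_filter_full_requirement():
    counts = pd.DataFrame([[1, 1, 0]], index=["g"])
    assert not de_mod.expression_fraction_filter(counts, min_frac=1.0)["g"]


def test_fraction_filter_empty_subset():
    counts = pd.DataFrame([[1]], index=["g"], columns=["c"])
    with pytest.raises(ValueError, match="empty"):
        de_mod.expression_fraction_filter(counts, cell_subset=[])


# --- BH ----------------------------------------------------------------------

def test_bh_hand_computed_example():
    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                  0.212, 0.216])
    # step-up by hand: q_i = min_{j>=i} p_j * 10 / j
    expect = np.array([0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.10571429,
                       0.216, 0.216, 0.216])
    q = de_mod.bh_adjust(p)
    assert np.allclose(q, expect, atol=1e-8)


def test_bh_nan_passthrough():
    q = de_mod.bh_adjust(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1])
    # NaN excluded from the denominator: m = 2
    assert np.isclose(q[0], 0.02)


# --- NB tests ----------------------------------------------------------------

def _pseudobulk(rng, n_genes=300, n_per_group=6, lfc_genes=0, lfc=1.0,
                phi=None):
    """Pseudobulk at the study's scale: ~1000 cells x ~1000 UMIs pooled per
    sample gives mean gene counts of a few hundred; per-gene NB
    overdispersion log-normal around 0.025, the typical within-genotype
    biological dispersion of inbred-mouse replicates."""
    n_cols = 2 * n_per_group
    cols = [f"s{i}|all" for i in range(n_cols)]
    design = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n_cols)],
        "group": "all",
        "genotype": ["control"] * n_per_group + ["double_mutant"] * n_per_group,
    }, index=cols)
    mu = rng.lognormal(5.5, 1.2, n_genes)
    sf = rng.lognormal(0, 0.3, n_cols)
    mu_mat = mu[:, None] * sf[None, :]
    if lfc_genes:
        mu_mat[:lfc_genes, n_per_group:] *= 2 ** lfc
    if phi is None:
        phi = rng.lognormal(np.log(0.025), 0.5, n_genes)[:, None]
    counts = rng.poisson(rng.gamma(1 / phi, mu_mat * phi))
    n_cells = pd.Series(rng.integers(50, 200, n_cols), index=cols)
    return PseudobulkTable(counts=pd.DataFrame(counts, columns=cols),
                           n_cells=n_cells, design=design)


def test_wald_recovers_planted_lfc(rng):
    # 5% of genes DE, as in a realistic screen; a much larger unidirectional
    # DE fraction would bias the median-of-ratios size factors themselves
    pb = _pseudobulk(rng, n_genes=600, lfc_genes=30, lfc=1.0)
    res = de_mod.nb_wald_test(pb, "genotype")
    lfc = res["log2fc"].astype(float)
    assert abs(lfc.iloc[:30].mean() - 1.0) < 0.15
    q = res["q"].astype(float)
    assert (q.iloc[:30] < 0.1).mean() >= 0.8


def test_wald_all_zero_gene_excluded(rng):
    pb = _pseudobulk(rng, n_genes=50)
    pb.counts.iloc[0] = 0
    res = de_mod.nb_wald_test(pb, "genotype")
    assert res.iloc[0]["status"] == "not_tested"
    assert np.isnan(float(res.iloc[0]["p"]) if res.iloc[0]["p"] is not np.nan
                    else np.nan)


def test_wald_requires_replicates():
    rng = np.random.default_rng(0)
    pb = _pseudobulk(rng, n_genes=10, n_per_group=6)
    pb.design.loc[:, "genotype"] = ["control"] + ["double_mutant"] * 11
    with pytest.raises(ValueError, match="fewer than 2"):
        de_mod.nb_wald_test(pb, "genotype")


def test_lrt_identical_columns_stat_zero(rng):
    n_cols = 8
    cols = [f"s{i % 2}|g{i // 2}" for i in range(n_cols)]
    design = pd.DataFrame({"sample": [f"s{i % 2}" for i in range(n_cols)],
                           "group": [f"g{i // 2}" for i in range(n_cols)]},
                          index=cols)
    counts = pd.DataFrame(np.full((5, n_cols), 40), columns=cols)
    pb = PseudobulkTable(counts=counts,
                         n_cells=pd.Series(50, index=cols), design=design)
    res = de_mod.nb_lrt_test(pb, "group")
    assert (res["stat"].astype(float) < 1e-4).all()


def test_lrt_planted_group_gene_top_ranked(rng):
    n_cols = 16
    cols = [f"s{i % 4}|g{i // 4}" for i in range(n_cols)]
    design = pd.DataFrame({"sample": [f"s{i % 4}" for i in range(n_cols)],
                           "group": [f"g{i // 4}" for i in range(n_cols)]},
                          index=cols)
    mu = rng.lognormal(3, 1, 100)
    mu_mat = np.tile(mu[:, None], (1, n_cols))
    mu_mat[0, :4] *= 16.0  # strong single-group gene
    counts = rng.poisson(rng.gamma(1 / 0.05, mu_mat * 0.05))
    pb = PseudobulkTable(counts=pd.DataFrame(counts, columns=cols),
                         n_cells=pd.Series(rng.integers(30, 80, n_cols),
                                           index=cols), design=design)
    res = de_mod.nb_lrt_test(pb, "group")
    q = res["q"].astype(float)
    assert q.iloc[0] <= q.quantile(0.02)


def test_wald_lrt_agree_two_groups(rng):
    """On a 2-group design Wald and LRT p-values agree closely."""
    pb = _pseudobulk(rng, n_genes=150, n_per_group=8, lfc_genes=40, lfc=0.8)
    wald = de_mod.nb_wald_test(pb, "genotype")
    design = pb.design.copy()
    design["group"] = design["genotype"]
    pb2 = PseudobulkTable(counts=pb.counts, n_cells=pb.n_cells, design=design)
    lrt = de_mod.nb_lrt_test(pb2, "group")
    pw = -np.log10(wald["p"].astype(float))
    pl = -np.log10(lrt["p"].astype(float))
    ok = pw.notna() & pl.notna() & np.isfinite(pw) & np.isfinite(pl)
    assert np.corrcoef(pw[ok], pl[ok])[0, 1] > 0.95


# --- composition test --------------------------------------------------------

def _composition(rng, beta_g=0.0, n_ctrl=12, n_mut=14, p0=0.1, re_sd=0.5,
                 cells=120):
    rows, design = [], []
    for i in range(n_ctrl + n_mut):
        g = "control" if i < n_ctrl else "double_mutant"
        eta = (np.log(p0 / (1 - p0)) + (beta_g if g == "double_mutant" else 0)
               + rng.normal(0, re_sd))
        y = rng.binomial(cells, expit(eta))
        rows.append({"sample": f"s{i}", "inA": y, "rest": cells - y})
        design.append({"sample": f"s{i}", "genotype": g,
                       "sex": "F" if i % 2 == 0 else "M",
                       "stage": "P40" if (i // 2) % 2 == 0 else "P90"})
    return (pd.DataFrame(rows).set_index("sample"),
            pd.DataFrame(design).set_index("sample"))


def test_composition_recovers_planted_odds(rng):
    comp, des = _composition(rng, beta_g=np.log(3), re_sd=0.3)
    res = de_mod.composition_test(comp, "inA", des)
    row = res.loc["genotype[double_mutant]"]
    assert row["p"] < 0.05
    assert abs(row["estimate"] - np.log(3)) < 0.8


def test_composition_separation_flagged(rng):
    comp, des = _composition(rng, beta_g=0.0)
    comp["inA"] = 0
    comp.loc["s20", "inA"] = 30  # cluster present in a single (mutant) sample
    res = de_mod.composition_test(comp, "inA", des)
    row = res.loc["genotype[double_mutant]"]
    assert row["status"] == "separation"
    assert np.isnan(row["p"])


def test_composition_too_few_samples(rng):
    comp, des = _composition(rng, n_ctrl=2, n_mut=14)
    with pytest.raises(ValueError, match="fewer than 3"):
        de_mod.composition_test(comp, "inA", des)


def test_composition_missing_cluster(rng):
    comp, des = _composition(rng)
    with pytest.raises(ValueError, match="not in composition"):
        de_mod.composition_test(comp, "missing", des)


# --- pooled vs bulk ----------------------------------------------------------

def test_pooled_vs_bulk_perfect_match(rng):
    genes = [f"g{i}" for i in range(200)]
    pooled = pd.DataFrame({"sc": rng.integers(1, 1000, 200)}, index=genes)
    tpm = pooled["sc"] / pooled["sc"].sum() * 1e6
    bulk = pd.DataFrame({"bulk": tpm}, index=genes)
    out = de_mod.pooled_vs_bulk_correlation(pooled, bulk)
    assert np.isclose(out["R"].iloc[0], 1.0)


def test_pooled_vs_bulk_independent_profiles(rng):
    genes = [f"g{i}" for i in range(5000)]
    pooled = pd.DataFrame({"sc": rng.integers(1, 500, 5000)}, index=genes)
    bulk = pd.DataFrame({"bulk": rng.lognormal(2, 1, 5000)}, index=genes)
    out = de_mod.pooled_vs_bulk_correlation(pooled, bulk)
    assert abs(out["R"].iloc[0]) < 0.1


def test_pooled_vs_bulk_floor_strict(rng):
    genes = ["g1", "g2", "g3"]
    pooled = pd.DataFrame({"sc": [100, 200, 300]}, index=genes)
    bulk = pd.DataFrame({"bulk": [1e-4, 5.0, 7.0]}, index=genes)  # g1 at floor
    out = de_mod.pooled_vs_bulk_correlation(pooled, bulk)
    assert out["n_genes"].iloc[0] == 2
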