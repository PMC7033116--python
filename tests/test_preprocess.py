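"""Knee selection, QC boundaries, normalization, HVG, PCA, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tumortraj import preprocess as pp
from tumortraj.simdata import simulate_barcode_mixture


# --- knee ------------------------------------------------------------------

def test_knee_recovers_planted_cells():
    tot, _ = simulate_barcode_mixture(500, 50000, seed=1)
    cut = pp.knee_select(tot)
    assert 400 <= cut <= 600


def test_knee_bimodal_exact():
    tot = np.array([1000.0] * 10 + [1.0] * 90)
    assert pp.knee_select(tot) == 10


def test_knee_scale_invariant():
    tot, _ = simulate_barcode_mixture(300, 20000, seed=3)
    assert pp.knee_select(tot) == pp.knee_select(tot * 7)


def test_knee_input_validation():
    with pytest.raises(ValueError, match="descending"):
        pp.knee_select(np.array([1.0, 5.0, 2.0]))
    with pytest.raises(ValueError, match="at least 3"):
        pp.knee_select(np.array([5.0, 1.0]))


# --- qc --------------------------------------------------------------------

def _toy_counts(detected, mito_frac, total=1000, n_genes=200, n_mito=10):
    """One cell with the requested detected-gene count and mito share."""
    col = np.zeros(n_genes)
    mito_counts = int(round(mito_frac * total))
    n_plain = detected - (1 if mito_counts > 0 else 0)
    col[n_mito:n_mito + n_plain] = (total - mito_counts) // n_plain
    col[n_mito] += (total - mito_counts) % n_plain
    col[0] = mito_counts
    names = [f"mt-{i}" for i in range(n_mito)] + [
        f"G{i}" for i in range(n_genes - n_mito)]
    counts = pd.DataFrame({"cell1": col}, index=pd.Index(names, name="gene"))
    genes = pd.DataFrame({"mito": [n.startswith("mt-") for n in names],
                          "ribo": False}, index=counts.index)
    return counts, genes


@pytest.mark.parametrize("detected,mito,kept", [
    (99, 0.0, False),     # below the at-least-100-genes floor
    (100, 0.15, False),   # mito exactly 15% -> removed (strict less-than)
    (100, 0.149, True),   # just under both boundaries -> kept
])
def test_qc_boundaries(detected, mito, kept):
    counts, genes = _toy_counts(detected, mito)
    mask, qc = pp.qc_filter(counts, pp.QCThresholds(), genes)
    assert qc.loc["cell1", "detected_genes"] == detected
    assert np.isclose(qc.loc["cell1", "mito_frac"], mito, atol=5e-4)
    assert bool(mask.loc["cell1"]) is kept


def test_qc_idempotent(small_dataset):
    counts, metadata, _ = small_dataset
    genes = metadata.attrs["genes"]
    mask, _ = pp.qc_filter(counts, genes=genes)
    filtered = counts.loc[:, mask.to_numpy()]
    mask2, _ = pp.qc_filter(filtered, genes=genes)
    assert mask2.all()


def test_qc_without_mito_flags_warns():
    counts, genes = _toy_counts(150, 0.5)
    genes["mito"] = False
    with pytest.warns(UserWarning, match="mito"):
        mask, _ = pp.qc_filter(counts, pp.QCThresholds(), genes)
    assert mask.loc["cell1"]  # mito criterion skipped


def test_qc_max_genes_strict():
    counts, genes = _toy_counts(150, 0.0)
    thr = pp.QCThresholds(min_genes=100, max_genes=150)
    mask, _ = pp.qc_filter(counts, thr, genes)
    assert not mask.loc["cell1"]  # "less than 150" excludes exactly 150


# --- normalize -------------------------------------------------------------

def test_normalize_hand_example():
    counts = pd.DataFrame({"c": [2, 0, 2]}, index=["g1", "g2", "g3"])
    expr = pp.normalize_log(counts, scale_factor=100)
    expect = [np.log1p(50.0), 0.0, np.log1p(50.0)]
    assert np.allclose(expr["c"], expect)


def test_normalize_expm1_rowsum_equals_scale():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(2.0, size=(50, 20)))
    counts.iloc[0] += 1  # no zero-depth cells
    expr = pp.normalize_log(counts, scale_factor=1e4)
    sums = np.expm1(expr.to_numpy()).sum(axis=0)
    assert np.allclose(sums, 1e4)


def test_normalize_identical_cells_identical_rows():
    counts = pd.DataFrame({"a": [1, 2, 3], "b": [2, 4, 6]})
    expr = pp.normalize_log(counts, 100)
    assert np.allclose(expr["a"], expr["b"])


def test_normalize_zero_depth_error():
    counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
    with pytest.raises(ValueError, match="empty"):
        pp.normalize_log(counts, 100)


def test_normalize_constant_covariate_noop():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.poisson(3.0, size=(30, 15)) + 1)
    cov = pd.DataFrame({"c": np.ones(15)})
    plain = pp.normalize_log(counts, 100)
    reg = pp.normalize_log(counts, 100, regress_covariates=cov)
    assert np.allclose(plain.to_numpy(), reg.to_numpy(), atol=1e-10)


def test_normalize_regression_removes_covariate_effect():
    rng = np.random.default_rng(3)
    depth_cov = rng.normal(size=40)
    base = rng.poisson(5.0, size=(25, 40)).astype(float) + 1
    counts = pd.DataFrame(np.round(base * np.exp(0.5 * depth_cov)).astype(int) + 1)
    expr = pp.normalize_log(counts, 100,
                            regress_covariates=pd.DataFrame({"d": depth_cov}))
    corr = [abs(np.corrcoef(expr.iloc[g], depth_cov)[0, 1])
            for g in range(25)]
    assert np.mean(corr) < 0.2


# --- hvg -------------------------------------------------------------------

def test_hvg_planted_bimodal_genes():
    rng = np.random.default_rng(4)
    n_cells = 300
    flat = rng.poisson(2.0, size=(1950, n_cells))
    group = rng.random(n_cells) < 0.5
    bimodal = np.where(group, rng.poisson(8.0, size=(50, n_cells)),
                       rng.poisson(0.3, size=(50, n_cells)))
    counts = pd.DataFrame(np.vstack([bimodal, flat]),
                          index=[f"sig{i}" for i in range(50)]
                          + [f"flat{i}" for i in range(1950)])
    counts.loc[:, counts.sum(axis=0) == 0] = 1
    expr = pp.normalize_log(counts, 1e4)
    top = pp.select_hvg(expr, 50)
    assert sum(g.startswith("sig") for g in top) >= 45


def test_hvg_identity_and_determinism():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(np.log1p(rng.poisson(3.0, size=(40, 30))) + 1e-9)
    assert set(pp.select_hvg(expr, 40)) == set(expr.index)
    assert list(pp.select_hvg(expr, 10)) == list(pp.select_hvg(expr, 10))


def test_hvg_too_many_requested():
    expr = pd.DataFrame(np.zeros((10, 5)))
    expr.iloc[0] = 1.0
    with pytest.raises(ValueError, match="expressed"):
        pp.select_hvg(expr, 5)


# --- pca -------------------------------------------------------------------

def test_pca_rank_two():
    rng = np.random.default_rng(6)
    basis = rng.normal(size=(2, 30))
    weights = rng.normal(size=(40, 2))
    expr = pd.DataFrame((weights @ basis).T)  # genes x cells, rank 2
    _, ev = pp.pca_embed(expr, 5)
    assert ev[2:].max() < 1e-20 * ev[0]


def test_pca_rotation_invariant_spectrum():
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.normal(size=(20, 50)))
    q, _ = np.linalg.qr(rng.normal(size=(20, 20)))
    rotated = pd.DataFrame(q @ expr.to_numpy())
    _, ev1 = pp.pca_embed(expr, 5)
    _, ev2 = pp.pca_embed(rotated, 5)
    assert np.allclose(ev1, ev2)


def test_pca_separates_populations():
    rng = np.random.default_rng(8)
    group = np.repeat([0, 1], 50)
    expr = pd.DataFrame(rng.normal(size=(30, 100)) + 4.0 * group[None, :]
                        * rng.choice([0, 1], size=(30, 1)))
    coords, _ = pp.pca_embed(expr, 2)
    r = np.corrcoef(coords["PC1"], group)[0, 1]
    assert abs(r) > 0.9


def test_pca_too_many_components():
    expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 8)))
    with pytest.raises(ValueError, match="n_pcs"):
        pp.pca_embed(expr, 9)


# --- significant pcs -------------------------------------------------------

def test_significant_pcs_pure_noise():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        expr = pd.DataFrame(rng.normal(size=(80, 120)))
        hits += pp.significant_pcs(expr, n_pcs=10, n_perm=30, seed=seed) == 0
    assert hits >= 4


def test_significant_pcs_planted_signals():
    rng = np.random.default_rng(9)
    n_cells, n_genes = 150, 100
    noise = rng.normal(size=(n_cells, n_genes))
    for j in range(3):
        pattern = rng.normal(size=n_cells)
        loading = np.zeros(n_genes)
        loading[j * 30:(j + 1) * 30] = 8.0
        noise += np.outer(pattern, loading)
    expr = pd.DataFrame(noise.T)
    assert pp.significant_pcs(expr, n_pcs=8, n_perm=30, seed=1) == 3


def test_significant_pcs_alpha_one():
    rng = np.random.default_rng(10)
    expr = pd.DataFrame(rng.normal(size=(30, 40)))
    assert pp.significant_pcs(expr, n_pcs=5, n_perm=20, alpha=1.0) == 5


# --- clustering / embedding -------------------------------------------------

def test_cluster_three_blobs(blobs):
    coords, labels = blobs
    found = pp.cluster_graph(coords, k_neighbors=15, resolution=1.0, seed=0)
    assert adjusted_rand_score(labels, found) == 1.0


def test_cluster_single_blob_low_resolution():
    rng = np.random.default_rng(11)
    coords = pd.DataFrame(rng.normal(size=(100, 4)))
    found = pp.cluster_graph(coords, k_neighbors=20, resolution=0.05, seed=0)
    assert found.nunique() == 1


def test_cluster_deterministic(blobs):
    coords, _ = blobs
    a = pp.cluster_graph(coords, 10, 1.0, seed=3)
    b = pp.cluster_graph(coords, 10, 1.0, seed=3)
    assert (a == b).all()


def test_cluster_too_few_cells():
    with pytest.raises(ValueError, match="k_neighbors"):
        pp.cluster_graph(pd.DataFrame(np.zeros((5, 2))), k_neighbors=10)


def test_embed_2d_blob_separation_and_determinism():
    rng = np.random.default_rng(12)
    pts = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(30, 1, (40, 5))])
    coords = pd.DataFrame(pts)
    emb = pp.embed_2d(coords, seed=0)
    emb2 = pp.embed_2d(coords, seed=0)
    assert np.allclose(emb.to_numpy(), emb2.to_numpy())
    a, b = emb.iloc[:40].mean(), emb.iloc[40:].mean()
    gap = np.linalg.norm(a - b)
    spread = np.linalg.norm(emb.iloc[:40] - a.to_numpy(), axis=1).mean()
    assert gap > 5 * spread


def test_embed_2d_too_few_cells():
    with pytest.raises(ValueError, match="10 cells"):
        pp.embed_2d(pd.DataFrame(np.zeros((5, 3))))


def test_merge_labels():
    labels = pd.Series(["acinar1", "acinar2", "ductal"])
    merged = pp.merge_labels(labels, {"acinar1": "acinar", "acinar2": "acinar"})
    assert list(merged) == ["acinar", "acinar", "ductal"]
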