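"""Reading and writing count matrices and per-cell tables.

Counts travel as Matrix Market triplets (matrix.mtx + genes.tsv +
barcodes.tsv, 10x-style) or dense TSV for toys; all tables are TSV with
header, UTF-8, no index column.  Gene flag columns (mitochondrial,
ribosomal) are attached from configurable symbol-prefix rules.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["read_counts", "write_counts", "flag_genes",
           "MITO_PREFIXES", "RIBO_PREFIXES"]

MITO_PREFIXES = ("mt-",)
RIBO_PREFIXES = ("Rps", "Rpl")


def flag_genes(gene_names, mito_prefixes=MITO_PREFIXES,
               ribo_prefixes=RIBO_PREFIXES) -> pd.DataFrame:
    """Gene table with boolean mito / ribo flags from symbol prefixes."""
    idx = pd.Index(gene_names, name="gene")
    lower = idx.str.lower()
    mito = np.zeros(len(idx), bool)
    for p in mito_prefixes:
        mito |= lower.str.startswith(p.lower())
    ribo = np.zeros(len(idx), bool)
    for p in ribo_prefixes:
        ribo |= idx.str.startswith(p)
    return pd.DataFrame({"mito": mito, "ribo": ribo}, index=idx)


def _validate_integer(mat: np.ndarray) -> np.ndarray:
    if not np.allclose(mat, np.round(mat), atol=0, rtol=0):
        bad = mat[mat != np.round(mat)]
        raise ValueError(f"count matrix has non-integer entries (e.g. {bad.flat[0]})")
    return mat.astype(np.int64)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x cells integer count matrix.

    ``path`` may be a directory holding matrix.mtx + genes.tsv +
    barcodes.tsv, or a dense TSV (first column = gene names, header =
    cell barcodes).  A transposed MTX whose dimensions match the gene
    and barcode tables the other way round is auto-oriented (logged).
    Non-integer entries are an error.  Mito/ribo flags are attached as
    ``counts.attrs['genes']``.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(f"{f} missing from MTX bundle")
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str)
        mat = spio.mmread(mtx)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if mat.shape == (len(genes), len(barcodes)):
            pass
        elif mat.shape == (len(barcodes), len(genes)):
            logger.info("read_counts: matrix stored cells x genes; transposing")
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"(genes={len(genes)}, cells={len(barcodes)}) nor its transpose")
        counts = pd.DataFrame(_validate_integer(mat), index=pd.Index(genes, name="gene"),
                              columns=barcodes)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = pd.DataFrame(_validate_integer(df.to_numpy(float)),
                              index=pd.Index(df.index.astype(str), name="gene"),
                              columns=df.columns.astype(str))
    counts.attrs["genes"] = flag_genes(counts.index)
    return counts


def write_counts(counts: pd.DataFrame, path, metadata: pd.DataFrame | None = None,
                 ground_truth: pd.DataFrame | None = None) -> None:
    """Write an MTX triplet bundle (plus optional metadata / truth TSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(counts.to_numpy())
    spio.mmwrite(path / "matrix.mtx", mat, field="integer")
    pd.Series(counts.index).to_csv(path / "genes.tsv", sep="\t", index=False,
                                   header=False)
    pd.Series(counts.columns).to_csv(path / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
    if metadata is not None:
        metadata.reset_index().to_csv(path / "metadata.tsv", sep="\t",
                                      index=False)
    if ground_truth is not None:
        ground_truth.reset_index().to_csv(path / "ground_truth.tsv", sep="\t",
                                          index=False)


def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a TSV with header; the index becomes an ordinary column."""
    out = df.reset_index() if df.index.name or index_label else df
    if index_label and out.columns[0] == "index":
        out = out.rename(columns={"index": index_label})
    out.to_csv(path, sep="\t", index=False)
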