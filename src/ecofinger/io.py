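"""Plain-text readers and writers for the pipeline's interchange formats.

Single-cell cohorts travel as a Matrix Market counts matrix with TSV
sidecars (genes.tsv: gene_id, chromosome, position; barcodes.tsv;
meta.tsv: cell_id, patient, region, true_type, true_malignant); bulk
cohorts as CSV (genes x samples) plus a survival CSV; spatial samples as
spot CSVs; marker sets as GMT.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse


def write_cohort(adata: AnnData, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), X.astype(np.int64))
    genes = adata.var.reset_index().rename(columns={"index": "gene_id"})
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False
    )
    meta = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    meta.to_csv(os.path.join(outdir, "meta.tsv"), sep="\t", index=False)


def read_cohort(indir: str) -> AnnData:
    X = spio.mmread(os.path.join(indir, "matrix.mtx")).tocsr()
    genes = pd.read_csv(
        os.path.join(indir, "genes.tsv"), sep="\t", index_col="gene_id"
    )
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")[
        "barcode"
    ]
    meta = pd.read_csv(
        os.path.join(indir, "meta.tsv"), sep="\t", index_col="cell_id"
    )
    adata = AnnData(
        X=np.asarray(X.todense(), dtype=np.int32),
        obs=meta.loc[barcodes],
        var=genes,
    )
    return adata


def write_gmt(signatures: dict, path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, description or name, *genes]) + "\n")


def read_gmt(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_bulk(expr: pd.DataFrame, survival: pd.DataFrame, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    expr.to_csv(os.path.join(outdir, "bulk_expression.csv"))
    survival.to_csv(os.path.join(outdir, "survival.csv"), index=False)


def read_bulk(outdir: str):
    expr = pd.read_csv(
        os.path.join(outdir, "bulk_expression.csv"), index_col=0
    )
    survival = pd.read_csv(os.path.join(outdir, "survival.csv"))
    return expr, survival


def write_lr_database(db: pd.DataFrame, path: str) -> None:
    db[["pair_id", "ligand", "receptor"]].to_csv(path, index=False)


def read_lr_database(path: str) -> pd.DataFrame:
    db = pd.read_csv(path)
    required = {"pair_id", "ligand", "receptor"}
    if not required <= set(db.columns):
        raise ValueError(f"LR database needs columns {sorted(required)}")
    if db["pair_id"].duplicated().any():
        raise ValueError("duplicate pair ids in LR database")
    return db


def write_spatial(sample: pd.DataFrame, path: str) -> None:
    sample.to_csv(path, index=False)


def read_spatial(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "x_px", "y_px", "gene", "copies"}
    if not required <= set(df.columns):
        raise ValueError(f"spot table needs columns {sorted(required)}")
    return df
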