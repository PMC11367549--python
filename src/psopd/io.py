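"""Readers and writers for the pipeline's on-disk formats.

Counts travel as a TSV (gene rows, header of sample ids) or as a
MatrixMarket triplet with sidecar row/column id files; metadata, serum and
PASI tables as CSV; gene sets as GMT (see :mod:`psopd.genesets`).
All readers validate ids and dtypes and raise typed errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .serum import validate_serum_table

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_meta", "write_meta",
    "read_serum", "write_serum",
    "read_hc", "write_hc",
    "read_pasi", "write_pasi",
    "read_truth", "write_truth",
]

TISSUES = {"lesional", "nonlesional"}


def _check_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return _check_counts(df)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    mat = sio.mmread(mtx_path)
    if sp.issparse(mat):
        mat = mat.toarray()
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    df = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    df.index.name = "gene"
    return _check_counts(df)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, genes_path, samples_path) -> None:
    sio.mmwrite(str(mtx_path), sp.csr_matrix(counts.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, counts.index)) + "\n")
    Path(samples_path).write_text("\n".join(map(str, counts.columns)) + "\n")


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                    "arm": str, "tissue": str})
    required = {"sample_id", "subject_id", "arm", "week", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["tissue"]) - TISSUES
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    dup = meta.duplicated(subset=["subject_id", "week", "tissue"])
    if dup.any():
        row = meta.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (subject, week, tissue): {row['subject_id']}/{row['week']}/{row['tissue']}"
        )
    meta["week"] = pd.to_numeric(meta["week"], errors="raise").astype(int)
    return meta


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_serum(path, npx: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str, "analyte": str})
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(int)
    return validate_serum_table(df, npx=npx)


def write_serum(serum: pd.DataFrame, path) -> None:
    serum.to_csv(path, index=False)


def read_hc(path, npx: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "analyte": str})
    value_col = "npx" if npx else "conc_pg_ml"
    required = {"subject_id", "analyte", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"healthy-control table missing columns: {sorted(missing)}")
    if not npx and (df[value_col] <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    return df


def write_hc(hc: pd.DataFrame, path) -> None:
    hc.to_csv(path, index=False)


def read_pasi(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str})
    required = {"subject_id", "week", "pasi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PASI table missing columns: {sorted(missing)}")
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(int)
    return df


def write_pasi(pasi: pd.DataFrame, path) -> None:
    pasi.to_csv(path, index=False)


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
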