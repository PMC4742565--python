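"""Reading and writing expression matrices and per-stage tables.

TSV matrices are cells x genes with the cell identifier in the first
column; MTX (Matrix Market) matrices are stored genes x cells in the
sparse convention with companion ``genes.tsv`` and ``cells.tsv``
one-column name files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def _validate(matrix: pd.DataFrame) -> pd.DataFrame:
    dup_cells = matrix.index[matrix.index.duplicated()].unique()
    dup_genes = matrix.columns[matrix.columns.duplicated()].unique()
    if len(dup_cells):
        raise ValueError(f"duplicate cell identifiers: {list(dup_cells[:5])}")
    if len(dup_genes):
        raise ValueError(f"duplicate gene identifiers: {list(dup_genes[:5])}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return matrix


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cell")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    # pandas mangles duplicate column names on read, so check the raw header
    header = pd.read_csv(path, sep="\t", header=None, nrows=1).iloc[0, 1:]
    dups = header[header.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return _validate(df)


def write_matrix_mtx(matrix: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(matrix.to_numpy().T))
    pd.Series(matrix.columns).to_csv(outdir / "genes.tsv", index=False, header=False)
    pd.Series(matrix.index).to_csv(outdir / "cells.tsv", index=False, header=False)


def read_matrix_mtx(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {indir / name}")
    values = np.asarray(spio.mmread(indir / "matrix.mtx").todense()).T
    genes = pd.read_csv(indir / "genes.tsv", header=None)[0].tolist()
    cells = pd.read_csv(indir / "cells.tsv", header=None)[0].tolist()
    if values.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    return _validate(pd.DataFrame(values, index=cells, columns=genes))


def read_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a matrix from TSV (file) or MTX (directory); format by inspection."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.is_dir() else "tsv"
    if fmt == "tsv":
        return read_matrix_tsv(path)
    if fmt == "mtx":
        return read_matrix_mtx(path)
    raise ValueError(f"unknown matrix format {fmt!r}")
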