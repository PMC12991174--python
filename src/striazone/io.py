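"""File formats and validated input loading.

Cell tables travel as CSV or Parquet (columns cell_id, x_um, y_um, donor,
cell_type, ...); count matrices as an MTX triplet with genes.tsv /
barcodes.tsv sidecars.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

__all__ = [
    "atomic_write",
    "write_cells",
    "read_cells",
    "write_counts_mtx",
    "read_counts_mtx",
    "read_inputs",
    "write_json",
    "read_json",
]

REQUIRED_CELL_COLS = ("cell_id", "x_um", "y_um", "donor", "cell_type")


def atomic_write(path, writer) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.stem}.",
                               suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_cells(cells: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        atomic_write(path, lambda t: cells.to_parquet(t))
    else:
        atomic_write(path, lambda t: cells.to_csv(t, index=False))


def read_cells(path) -> pd.DataFrame:
    path = Path(path)
    cells = (pd.read_parquet(path) if path.suffix == ".parquet"
             else pd.read_csv(path))
    missing = [c for c in REQUIRED_CELL_COLS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell ids: {sorted(set(dup))[:5]}")
    if not np.isfinite(cells[["x_um", "y_um"]].to_numpy(float)).all():
        raise ValueError("non-finite coordinates (expected μm)")
    return cells


def write_counts_mtx(X: sparse.spmatrix, gene_names, cell_ids, outdir) -> None:
    """Write a genes x cells MTX triplet (input X is cells x genes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atomic_write(outdir / "matrix.mtx",
                 lambda t: sio.mmwrite(t, sparse.csr_matrix(X).T))
    atomic_write(outdir / "genes.tsv", lambda t: Path(t).write_text(
        "\n".join(gene_names) + "\n"))
    atomic_write(outdir / "barcodes.tsv", lambda t: Path(t).write_text(
        "\n".join(cell_ids) + "\n"))


def read_counts_mtx(outdir) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read an MTX triplet; returns (cells x genes CSR, genes, barcodes)."""
    outdir = Path(outdir)
    mtx_path = outdir / "matrix.mtx"
    if not mtx_path.exists():
        mtx_path = outdir / "matrix.mtx.gz"
    M = sio.mmread(mtx_path).tocsr()
    genes = (outdir / "genes.tsv").read_text().splitlines()
    cells = (outdir / "barcodes.tsv").read_text().splitlines()
    if M.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix {M.shape} does not match {len(genes)} genes x "
            f"{len(cells)} barcodes")
    return sparse.csr_matrix(M.T), genes, cells


def read_inputs(cells_path, counts_dir):
    """Load and cross-validate the cell table and count matrix."""
    cells = read_cells(cells_path)
    X, genes, barcodes = read_counts_mtx(counts_dir)
    cid = cells["cell_id"].tolist()
    if cid != barcodes:
        extra = sorted(set(barcodes) ^ set(cid))[:5]
        raise ValueError(f"barcodes/cell-table mismatch, e.g. {extra}")
    return cells, X, genes


def write_json(obj, path) -> None:
    atomic_write(path, lambda t: Path(t).write_text(
        json.dumps(obj, indent=2, default=_jsonable) + "\n"))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, tuple)):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
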